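"""Cα structure I/O, superposition, alignment maps and motif definitions.

The universal in-memory currency is :class:`Structure`: an ordered list of Cα
atoms whose file order defines the global index ``0..N-1`` used by every
downstream array (TSV and PDB output is 1-based, as is conventional).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

__all__ = [
    "Structure",
    "AlignmentMap",
    "MotifDefinition",
    "Pathway",
    "read_calpha_pdb",
    "write_calpha_pdb",
    "write_pathway_pdb",
    "read_pathway_pdb",
    "kabsch",
    "superpose",
    "parse_alignment",
    "write_alignment",
    "identity_alignment",
    "alignment_from_fasta",
    "read_motifs",
    "write_motifs",
]


# ---------------------------------------------------------------------------
# domain types
# ---------------------------------------------------------------------------


@dataclass(frozen=True)
class Structure:
    """An ordered Cα-only model of a (multi-chain) protein assembly.

    Parameters
    ----------
    chain_ids, resnums, resnames
        Per-atom chain identifier, residue number and 3-letter residue name.
    coords
        ``(N, 3)`` Cartesian coordinates in Å.
    label
        Free-text provenance tag (file name, fixture name, ...).
    """

    chain_ids: np.ndarray
    resnums: np.ndarray
    resnames: np.ndarray
    coords: np.ndarray
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "chain_ids", np.asarray(self.chain_ids, dtype=object))
        object.__setattr__(self, "resnums", np.asarray(self.resnums, dtype=int))
        object.__setattr__(self, "resnames", np.asarray(self.resnames, dtype=object))
        object.__setattr__(self, "coords", np.asarray(self.coords, dtype=float))
        n = len(self.chain_ids)
        if not (len(self.resnums) == len(self.resnames) == self.coords.shape[0] == n):
            raise ValueError("field lengths disagree")
        if self.coords.ndim != 2 or self.coords.shape[1] != 3:
            raise ValueError("coords must be (N, 3)")
        if not np.all(np.isfinite(self.coords)):
            raise ValueError("non-finite coordinates")
        keys = list(zip(self.chain_ids, self.resnums))
        if len(set(keys)) != n:
            raise ValueError("duplicate (chain, residue number) entries")

    @property
    def n_atoms(self) -> int:
        return self.coords.shape[0]

    @property
    def chains(self) -> list[str]:
        """Unique chain ids in first-appearance order."""
        seen: dict[str, None] = {}
        for c in self.chain_ids:
            seen.setdefault(c, None)
        return list(seen)

    def index_of(self, chain_id: str, resnum: int) -> int:
        """Global 0-based index of a residue; KeyError if absent."""
        hits = np.flatnonzero((self.chain_ids == chain_id) & (self.resnums == resnum))
        if hits.size == 0:
            raise KeyError(f"residue {chain_id}/{resnum} not in structure")
        return int(hits[0])

    def with_coords(self, coords: np.ndarray, label: str | None = None) -> "Structure":
        return replace(
            self,
            coords=np.asarray(coords, dtype=float).reshape(self.n_atoms, 3),
            label=self.label if label is None else label,
        )

    def select(self, mask: np.ndarray) -> "Structure":
        mask = np.asarray(mask)
        return Structure(
            self.chain_ids[mask],
            self.resnums[mask],
            self.resnames[mask],
            self.coords[mask],
            self.label,
        )


@dataclass(frozen=True)
class AlignmentMap:
    """One-to-one residue correspondence between a begin and an end structure.

    ``pairs`` holds 0-based global indices, shape ``(n_pairs, 2)`` with the
    begin index in column 0. The unaligned sets are the complements.
    """

    pairs: np.ndarray
    unaligned_begin: frozenset
    unaligned_end: frozenset

    def __post_init__(self) -> None:
        object.__setattr__(self, "pairs", np.asarray(self.pairs, dtype=int).reshape(-1, 2))
        for col in (0, 1):
            vals = self.pairs[:, col]
            if len(np.unique(vals)) != len(vals):
                raise ValueError("alignment map is not one-to-one")

    @property
    def begin_indices(self) -> np.ndarray:
        return self.pairs[:, 0]

    @property
    def end_indices(self) -> np.ndarray:
        return self.pairs[:, 1]

    @property
    def n_pairs(self) -> int:
        return self.pairs.shape[0]


@dataclass(frozen=True)
class MotifDefinition:
    """A named inclusive residue-number range, on all chains or one chain."""

    name: str
    chain_scope: str  # "*" for all chains, else a chain id
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.end < self.start:
            raise ValueError(f"motif {self.name}: empty residue range")

    def indices(self, structure: Structure) -> np.ndarray:
        """Global indices of member residues present in `structure`."""
        mask = (structure.resnums >= self.start) & (structure.resnums <= self.end)
        if self.chain_scope != "*":
            mask &= structure.chain_ids == self.chain_scope
        return np.flatnonzero(mask)


@dataclass
class Pathway:
    """An ordered series of conformations tracing a conformational transition.

    ``conformations`` has shape ``(M, N, 3)`` in the begin structure's atom
    order; ``lambdas`` is the interpolation parameter per conformation
    (1 at the begin end, 0 at the end); ``cumulative_length`` is the arc
    length in Å measured by summed consecutive all-atom RMSDs.
    """

    conformations: np.ndarray
    lambdas: np.ndarray
    cumulative_length: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.conformations = np.asarray(self.conformations, dtype=float)
        if self.conformations.ndim != 3:
            raise ValueError("conformations must be (M, N, 3)")
        self.lambdas = np.asarray(self.lambdas, dtype=float)
        if self.cumulative_length is None:
            self.cumulative_length = cumulative_path_length(self.conformations)
        else:
            self.cumulative_length = np.asarray(self.cumulative_length, dtype=float)

    @property
    def n_conformations(self) -> int:
        return self.conformations.shape[0]

    @property
    def total_length(self) -> float:
        return float(self.cumulative_length[-1])

    def reversed(self) -> "Pathway":
        return Pathway(
            self.conformations[::-1].copy(),
            1.0 - self.lambdas[::-1],
            self.total_length - self.cumulative_length[::-1],
        )


def cumulative_path_length(conformations: np.ndarray) -> np.ndarray:
    """Arc length along a conformation series via consecutive all-atom RMSDs."""
    conformations = np.asarray(conformations, dtype=float)
    diffs = conformations[1:] - conformations[:-1]
    steps = np.sqrt(np.mean(np.sum(diffs**2, axis=2), axis=1))
    return np.concatenate([[0.0], np.cumsum(steps)])


# ---------------------------------------------------------------------------
# PDB I/O
# ---------------------------------------------------------------------------


def _residues_from_model(model, chain_filter=None):
    """Yield (chain_id, resnum, resname, ca_coord) applying altloc/icode rules."""
    seen: set[tuple[str, int]] = set()
    for chain in model:
        cid = chain.id
        if chain_filter is not None and cid not in chain_filter:
            continue
        for residue in chain:
            if "CA" not in residue:
                continue
            het, resseq, icode = residue.id
            if het == "W":
                continue
            key = (cid, resseq)
            if key in seen:
                # insertion-code duplicate: first Cα record wins
                log.warning("duplicate residue %s/%s (icode %r): keeping first", cid, resseq, icode)
                continue
            atom = residue["CA"]
            if atom.is_disordered():
                # highest occupancy, ties broken by altloc letter
                children = sorted(
                    atom.disordered_get_list(),
                    key=lambda a: (-(a.get_occupancy() or 0.0), a.get_altloc()),
                )
                atom = children[0]
                log.warning("altloc on %s/%s: keeping %r", cid, resseq, atom.get_altloc())
            seen.add(key)
            yield cid, resseq, residue.get_resname(), atom.get_coord()


def read_calpha_pdb(path, chain_filter=None, model_index: int = 0) -> Structure:
    """Read the Cα trace of a PDB file as a :class:`Structure`.

    One atom per residue; alternate locations resolve to the highest-occupancy
    record (ties by altloc letter) and insertion-code duplicates to the first
    Cα record, both logged.
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        model = parser.get_structure("s", str(path))[model_index]
    rows = list(_residues_from_model(model, chain_filter))
    if not rows:
        raise ValueError(f"no Cα atoms found in {path}")
    cids, nums, names, xyz = zip(*rows)
    return Structure(np.array(cids, dtype=object), nums, names, np.array(xyz, dtype=float), label=str(path))


def _pdb_atom_line(serial: int, resname: str, chain: str, resnum: int, xyz, bfactor: float) -> str:
    return (
        f"ATOM  {serial % 100000:5d}  CA  {resname:<3s} {chain[:1]:1s}{resnum % 10000:4d}    "
        f"{xyz[0]:8.3f}{xyz[1]:8.3f}{xyz[2]:8.3f}{1.00:6.2f}{bfactor:6.2f}           C  \n"
    )


def write_calpha_pdb(structure: Structure, path, bfactors: np.ndarray | None = None) -> None:
    """Write a Cα-only PDB; ``bfactors`` fills the B-factor column (e.g. for
    per-residue progress coloring)."""
    b = np.zeros(structure.n_atoms) if bfactors is None else np.asarray(bfactors, dtype=float)
    with open(path, "w") as fh:
        prev_chain = None
        for i in range(structure.n_atoms):
            if prev_chain is not None and structure.chain_ids[i] != prev_chain:
                fh.write("TER\n")
            prev_chain = structure.chain_ids[i]
            fh.write(
                _pdb_atom_line(
                    i + 1,
                    str(structure.resnames[i]),
                    str(structure.chain_ids[i]),
                    int(structure.resnums[i]),
                    structure.coords[i],
                    0.0 if not np.isfinite(b[i]) else float(b[i]),
                )
            )
        fh.write("END\n")


def write_pathway_pdb(pathway: Pathway, template: Structure, path) -> None:
    """Write a pathway as a multi-model PDB (one MODEL per conformation)."""
    if pathway.n_conformations == 0:
        raise ValueError("empty pathway")
    if pathway.conformations.shape[1] != template.n_atoms:
        raise ValueError("conformation length does not match template atom count")
    with open(path, "w") as fh:
        for m in range(pathway.n_conformations):
            fh.write(f"MODEL {m + 1:8d}\n")
            for i in range(template.n_atoms):
                fh.write(
                    _pdb_atom_line(
                        i + 1,
                        str(template.resnames[i]),
                        str(template.chain_ids[i]),
                        int(template.resnums[i]),
                        pathway.conformations[m, i],
                        0.0,
                    )
                )
            fh.write("ENDMDL\n")
        fh.write("END\n")


def read_pathway_pdb(path, template: Structure | None = None) -> Pathway:
    """Read a multi-model Cα PDB back into a :class:`Pathway`.

    Lambdas are not stored in PDB; they are filled with a uniform descending
    grid (use the TSV side-car for exact values).
    """
    from Bio.PDB import PDBParser

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        parser = PDBParser(QUIET=True)
        models = list(parser.get_structure("p", str(path)))
    confs = []
    for model in models:
        rows = list(_residues_from_model(model))
        confs.append(np.array([r[3] for r in rows], dtype=float))
    arr = np.array(confs)
    if template is not None and arr.shape[1] != template.n_atoms:
        raise ValueError("pathway atom count does not match template")
    lambdas = np.linspace(1.0, 0.0, arr.shape[0]) if arr.shape[0] > 1 else np.array([1.0])
    return Pathway(arr, lambdas)


# ---------------------------------------------------------------------------
# superposition
# ---------------------------------------------------------------------------


def kabsch(mobile: np.ndarray, target: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition of `mobile` onto `target`.

    Returns (rotation 3x3, translation 3-vector, rmsd) such that
    ``mobile @ R.T + t`` best fits `target` with uniform weights.
    """
    mobile = np.asarray(mobile, dtype=float)
    target = np.asarray(target, dtype=float)
    if mobile.shape[0] < 3:
        raise ValueError("need at least 3 points")
    cm, ct = mobile.mean(axis=0), target.mean(axis=0)
    P, Q = mobile - cm, target - ct
    # collinearity check: rank of the centered point cloud
    if np.linalg.matrix_rank(P, tol=1e-8) < 2 or np.linalg.matrix_rank(Q, tol=1e-8) < 2:
        raise ValueError("degenerate (collinear) point set")
    H = P.T @ Q
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = ct - R @ cm
    fitted = mobile @ R.T + t
    rmsd = float(np.sqrt(np.mean(np.sum((fitted - target) ** 2, axis=1))))
    return R, t, rmsd


def superpose(mobile: Structure, target: Structure, amap: AlignmentMap | None = None):
    """Rigid-body superpose `mobile` onto `target` over aligned pairs.

    With ``amap=None`` an index-wise identity correspondence is assumed.
    Returns ``(superposed_mobile, rmsd_over_aligned_pairs)``.
    """
    if amap is None:
        if mobile.n_atoms != target.n_atoms:
            raise ValueError("structures differ in size; supply an alignment map")
        bi = np.arange(mobile.n_atoms)
        ei = bi
    else:
        bi, ei = amap.begin_indices, amap.end_indices
    R, t, rmsd = kabsch(mobile.coords[bi], target.coords[ei])
    return mobile.with_coords(mobile.coords @ R.T + t), rmsd


# ---------------------------------------------------------------------------
# alignment maps
# ---------------------------------------------------------------------------

_ALN_COLS = ["begin_chain", "begin_resnum", "end_chain", "end_resnum"]


def _build_map(rows, begin: Structure, end: Structure) -> AlignmentMap:
    pairs = []
    for bc, br, ec, er in rows:
        pairs.append((begin.index_of(str(bc), int(br)), end.index_of(str(ec), int(er))))
    pairs = np.array(pairs, dtype=int).reshape(-1, 2)
    chain_map: dict[str, str] = {}
    for b, e in pairs:
        bc, ec = begin.chain_ids[b], end.chain_ids[e]
        if chain_map.setdefault(bc, ec) != ec:
            raise ValueError(f"begin chain {bc!r} maps to multiple end chains")
    un_b = frozenset(set(range(begin.n_atoms)) - set(pairs[:, 0].tolist()))
    un_e = frozenset(set(range(end.n_atoms)) - set(pairs[:, 1].tolist()))
    return AlignmentMap(pairs, un_b, un_e)


def parse_alignment(path, begin: Structure, end: Structure) -> AlignmentMap:
    """Parse a 4-column alignment TSV (begin_chain, begin_resnum, end_chain,
    end_resnum) into a validated :class:`AlignmentMap`."""
    df = pd.read_csv(path, sep="\t", comment="#")
    missing = [c for c in _ALN_COLS if c not in df.columns]
    if missing:
        raise ValueError(f"alignment TSV missing columns {missing}")
    return _build_map(df[_ALN_COLS].itertuples(index=False), begin, end)


def write_alignment(amap: AlignmentMap, begin: Structure, end: Structure, path) -> None:
    rows = [
        (begin.chain_ids[b], begin.resnums[b], end.chain_ids[e], end.resnums[e])
        for b, e in amap.pairs
    ]
    pd.DataFrame(rows, columns=_ALN_COLS).to_csv(path, sep="\t", index=False)


def identity_alignment(begin: Structure, end: Structure) -> AlignmentMap:
    """Match residues by (chain, resnum); residues present on only one side
    fall into the unaligned sets."""
    end_lookup = {(c, r): i for i, (c, r) in enumerate(zip(end.chain_ids, end.resnums))}
    rows = []
    for i, (c, r) in enumerate(zip(begin.chain_ids, begin.resnums)):
        j = end_lookup.get((c, r))
        if j is not None:
            rows.append((i, j))
    pairs = np.array(rows, dtype=int).reshape(-1, 2)
    un_b = frozenset(set(range(begin.n_atoms)) - set(pairs[:, 0].tolist()))
    un_e = frozenset(set(range(end.n_atoms)) - set(pairs[:, 1].tolist()))
    return AlignmentMap(pairs, un_b, un_e)


def alignment_from_fasta(path, begin: Structure, end: Structure,
                         begin_chains=None, end_chains=None) -> AlignmentMap:
    """Convert a gapped pairwise FASTA alignment into an AlignmentMap.

    The two records are read in order (begin first). Ungapped columns pair the
    k-th begin residue with the k-th end residue chain by chain; the chain
    lists default to each structure's chains in order, consumed sequentially.
    """
    from Bio import SeqIO

    records = list(SeqIO.parse(str(path), "fasta"))
    if len(records) != 2:
        raise ValueError("expected exactly two records in pairwise FASTA")
    sb, se = str(records[0].seq), str(records[1].seq)
    if len(sb) != len(se):
        raise ValueError("aligned sequences differ in length")
    begin_chains = list(begin.chains if begin_chains is None else begin_chains)
    end_chains = list(end.chains if end_chains is None else end_chains)
    bidx = np.concatenate([np.flatnonzero(begin.chain_ids == c) for c in begin_chains])
    eidx = np.concatenate([np.flatnonzero(end.chain_ids == c) for c in end_chains])
    pb = pe = 0
    rows = []
    for cb, ce in zip(sb, se):
        ib = bidx[pb] if cb != "-" else None
        ie = eidx[pe] if ce != "-" else None
        if cb != "-":
            pb += 1
        if ce != "-":
            pe += 1
        if ib is not None and ie is not None:
            rows.append(
                (begin.chain_ids[ib], begin.resnums[ib], end.chain_ids[ie], end.resnums[ie])
            )
    return _build_map(rows, begin, end)


# ---------------------------------------------------------------------------
# motifs
# ---------------------------------------------------------------------------


def read_motifs(path) -> list[MotifDefinition]:
    """Read motif definitions from a TSV (name, chain_scope, start_resnum,
    end_resnum); chain_scope ``*`` means every chain."""
    df = pd.read_csv(path, sep="\t", comment="#")
    need = ["name", "chain_scope", "start_resnum", "end_resnum"]
    missing = [c for c in need if c not in df.columns]
    if missing:
        raise ValueError(f"motif TSV missing columns {missing}")
    return [
        MotifDefinition(str(r.name), str(r.chain_scope), int(r.start_resnum), int(r.end_resnum))
        for r in df[need].itertuples(index=False)
    ]


def write_motifs(motifs, path) -> None:
    pd.DataFrame(
        [(m.name, m.chain_scope, m.start, m.end) for m in motifs],
        columns=["name", "chain_scope", "start_resnum", "end_resnum"],
    ).to_csv(path, sep="\t", index=False)
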