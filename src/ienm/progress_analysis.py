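"""Motional order along a transition pathway.

A conformation's *fractional progress* f is its arc-length position along the
pathway: f = l / L where l is the summed consecutive-RMSD length from the
begin conformation and L the total length. Each residue is then assigned the
f value of its *crossover conformation* — the first point on the pathway
where its Cα is equidistant from its begin and end positions. Low f means the
residue moves early in the transition, high f late. Motif averages of f are
directly comparable with experimental Φ values (high Φ ≈ early motion, so f
is compared against 1 − Φ).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from .structures_io import MotifDefinition, Pathway, Structure

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_DISPLACEMENT_FLOOR",
    "ELIC_MOTIFS",
    "ELIC_PHI",
    "f_progress",
    "crossover_f",
    "progress_table",
    "motif_mean",
    "order_correlation",
    "load_phi_table",
]

#: residues whose begin→end Cα displacement is below this (Å) get no
#: crossover value — equidistance is meaningless for a near-static residue
DEFAULT_DISPLACEMENT_FLOOR = 0.5

#: key secondary-structure elements of the ELIC subunit (residue ranges on
#: every chain), for reproducing the motif-average analysis
ELIC_MOTIFS = [
    MotifDefinition("loop A", "*", 79, 82),
    MotifDefinition("loop B", "*", 132, 137),
    MotifDefinition("loop C", "*", 174, 185),
    MotifDefinition("loop 2", "*", 28, 31),
    MotifDefinition("loop 7", "*", 112, 122),
    MotifDefinition("loop 9", "*", 147, 159),
    MotifDefinition("M1", "*", 201, 219),
    MotifDefinition("M2", "*", 227, 251),
    MotifDefinition("M3", "*", 260, 282),
    MotifDefinition("M4", "*", 296, 316),
    MotifDefinition("M2-M3 linker", "*", 252, 259),
]

#: motif-level experimental Φ values for the nAChR α subunit (channel-opening
#: rate-equilibrium analysis); shipped for the f vs. 1−Φ comparison
ELIC_PHI = {
    "loop A": 0.93,
    "loop B": 0.93,
    "loop C": 0.93,
    "loop 2": 0.75,
    "loop 7": 0.75,
    "M2": 0.65,
    "M4": 0.54,
    "M3": 0.32,
}


def f_progress(pathway: Pathway, conformation_index: int) -> float:
    """Fractional arc-length position of one conformation (0 at begin, 1 at end)."""
    L = pathway.total_length
    if L <= 0:
        raise ValueError("zero-length pathway")
    return float(pathway.cumulative_length[conformation_index] / L)


def crossover_f(
    pathway: Pathway,
    residue: int,
    floor: float = DEFAULT_DISPLACEMENT_FLOOR,
    end_positions: np.ndarray | None = None,
) -> float:
    """f value of the residue's crossover conformation, or NaN if undefined.

    The crossover is the first pathway point where the residue's Cα is
    equidistant from its begin and end positions, located by the first sign
    change of ``g(t) = |x(t) − x_begin| − |x(t) − x_end|`` with linear
    interpolation of f between the bracketing conformations. Residues whose
    total displacement is below `floor` are undefined (NaN).
    """
    if pathway.n_conformations < 2:
        raise ValueError("pathway needs at least two conformations")
    traj = pathway.conformations[:, residue, :]
    p0 = pathway.conformations[0, residue]
    p1 = (pathway.conformations[-1] if end_positions is None else end_positions)[residue]
    if np.linalg.norm(p1 - p0) < floor:
        return float("nan")
    g = np.linalg.norm(traj - p0, axis=1) - np.linalg.norm(traj - p1, axis=1)
    sign_change = np.flatnonzero((g[:-1] < 0) & (g[1:] >= 0))
    if sign_change.size == 0:
        log.info("residue %d never crosses equidistance; undefined", residue)
        return float("nan")
    m = int(sign_change[0])
    f0, f1 = f_progress(pathway, m), f_progress(pathway, m + 1)
    denom = g[m + 1] - g[m]
    w = 0.0 if denom == 0 else -g[m] / denom
    return float(f0 + w * (f1 - f0))


def progress_table(
    pathway: Pathway,
    structure: Structure,
    floor: float = DEFAULT_DISPLACEMENT_FLOOR,
    end_positions: np.ndarray | None = None,
) -> pd.DataFrame:
    """Per-residue crossover table: index, chain, resnum, displacement, f_cross."""
    n = structure.n_atoms
    if pathway.conformations.shape[1] != n:
        raise ValueError("pathway does not match structure atom count")
    endp = pathway.conformations[-1] if end_positions is None else end_positions
    disp = np.linalg.norm(endp - pathway.conformations[0], axis=1)
    f = np.array(
        [crossover_f(pathway, i, floor, end_positions) for i in range(n)]
    )
    return pd.DataFrame(
        {
            "index": np.arange(n),
            "chain": structure.chain_ids,
            "resnum": structure.resnums,
            "displacement": disp,
            "f_cross": f,
        }
    )


def motif_mean(
    progress: pd.DataFrame,
    motifs: list[MotifDefinition],
    structure: Structure,
) -> pd.DataFrame:
    """Arithmetic mean of defined f_cross over each motif's member residues
    (across all chains in scope); motifs with no defined member yield NaN."""
    rows = []
    f = progress["f_cross"].to_numpy()
    for m in motifs:
        idx = m.indices(structure)
        vals = f[idx]
        vals = vals[np.isfinite(vals)]
        if vals.size == 0:
            log.warning("motif %s has no residues with defined crossover", m.name)
            rows.append((m.name, float("nan"), 0))
        else:
            rows.append((m.name, float(np.mean(vals)), int(vals.size)))
    return pd.DataFrame(rows, columns=["motif", "mean_f_cross", "n_defined"])


def order_correlation(motif_f, phi) -> float:
    """Pearson correlation between motif-mean f and 1 − Φ over shared motifs.

    `motif_f` is a mapping or a `motif_mean` frame; `phi` a mapping or a
    2-column (label, phi) frame. High Φ means early motion, so agreement in
    motional order appears as positive correlation of f with 1 − Φ.
    """
    if isinstance(motif_f, pd.DataFrame):
        motif_f = dict(zip(motif_f["motif"], motif_f["mean_f_cross"]))
    if isinstance(phi, pd.DataFrame):
        phi = dict(zip(phi.iloc[:, 0], phi.iloc[:, 1]))
    common = [k for k in motif_f if k in phi and np.isfinite(motif_f[k])]
    if len(common) < 3:
        raise ValueError("need at least 3 motifs common to both tables")
    x = np.array([motif_f[k] for k in common])
    y = np.array([1.0 - phi[k] for k in common])
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        raise ValueError("constant input; correlation undefined")
    return float(stats.pearsonr(x, y).statistic)


def load_phi_table(path) -> pd.DataFrame:
    """Read a user Φ table: TSV with columns (label, phi), phi in [0, 1]."""
    df = pd.read_csv(path, sep="\t", comment="#")
    if df.shape[1] < 2:
        raise ValueError("phi TSV needs (label, phi) columns")
    df = df.iloc[:, :2]
    df.columns = ["label", "phi"]
    if ((df["phi"] < 0) | (df["phi"] > 1)).any():
        raise ValueError("phi values must lie in [0, 1]")
    return df
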