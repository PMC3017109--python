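"""Spring-masking perturbation analysis of transition pathways.

To probe which elastic interactions dictate the predicted order of events,
selected non-bonded springs are switched off (in both endpoint wells, by
default) and the pathway is re-solved; shifts in motif-average crossover f
report which couplings were load-bearing. Backbone (bonded) springs are never
severed — cutting the chain is physically meaningless at this resolution.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import progress_analysis
from .ienm_path import SolverSettings, make_double_well, solve_pathway
from .structures_io import AlignmentMap, MotifDefinition, Structure

log = logging.getLogger(__name__)

__all__ = ["PerturbationSpec", "expand_mask", "perturbed_progress", "perturbation_grid"]

_RULES = ("intra_subunit", "inter_subunit", "any")


@dataclass(frozen=True)
class PerturbationSpec:
    """A named rule generating the set of residue pairs to unspring.

    ``rule`` restricts pairs (one member in `set_a`, the other in `set_b`) to
    the same chain ("intra_subunit"), different chains ("inter_subunit"), or
    no restriction ("any"). Loop-mediated domain perturbations are expressed
    as intra_subunit rules with the loop as one set and the partner domain as
    the other.
    """

    name: str
    rule: str
    set_a: tuple[MotifDefinition, ...]
    set_b: tuple[MotifDefinition, ...]

    def __post_init__(self) -> None:
        if self.rule not in _RULES:
            raise ValueError(f"rule must be one of {_RULES}")


def _selection(motifs, structure: Structure) -> np.ndarray:
    if not motifs:
        return np.zeros(0, dtype=int)
    idx = np.concatenate([m.indices(structure) for m in motifs])
    return np.unique(idx)


def expand_mask(spec: PerturbationSpec, structure: Structure) -> set[tuple[int, int]]:
    """Explicit (i, j) pair set (i < j, 0-based) selected by the rule.

    The mask enumerates every candidate residue pair; `build_enm` ignores
    masked pairs that carry no spring, so the mask need not be pre-filtered
    by the cutoff. Bonded pairs are never removed downstream.
    """
    a = _selection(spec.set_a, structure)
    b = _selection(spec.set_b, structure)
    if a.size == 0 or b.size == 0:
        log.warning("perturbation %r selects no pairs (empty residue set)", spec.name)
        return set()
    chains = structure.chain_ids
    pairs: set[tuple[int, int]] = set()
    for i in a.tolist():
        for j in b.tolist():
            if i == j:
                continue
            same = chains[i] == chains[j]
            if spec.rule == "intra_subunit" and not same:
                continue
            if spec.rule == "inter_subunit" and same:
                continue
            pairs.add((min(i, j), max(i, j)))
    if not pairs:
        log.warning("perturbation %r produced an empty mask (no-op)", spec.name)
    return pairs


def perturbed_progress(
    begin: Structure,
    end: Structure,
    amap: AlignmentMap | None,
    spec: PerturbationSpec,
    motifs: list[MotifDefinition],
    settings: SolverSettings = SolverSettings(),
    baseline: pd.DataFrame | None = None,
    mask_wells: str = "both",
    floor: float = progress_analysis.DEFAULT_DISPLACEMENT_FLOOR,
    **well_kwargs,
) -> pd.DataFrame:
    """Re-solve the pathway with `spec`'s springs masked and aggregate motifs.

    Returns the motif table with columns (motif, mean_f_cross, n_defined) and,
    when a `baseline` motif table is given, a signed ``delta`` column of
    perturbed − unperturbed means.
    """
    mask = expand_mask(spec, begin)
    dw = make_double_well(begin, end, amap, masked_pairs=mask, mask_wells=mask_wells, **well_kwargs)
    pathway = solve_pathway(dw, settings)
    table = progress_analysis.progress_table(pathway, begin, floor=floor)
    per_motif = progress_analysis.motif_mean(table, motifs, begin)
    per_motif.insert(0, "perturbation", spec.name)
    if baseline is not None:
        base = dict(zip(baseline["motif"], baseline["mean_f_cross"]))
        per_motif["delta"] = [
            m - base.get(name, float("nan"))
            for name, m in zip(per_motif["motif"], per_motif["mean_f_cross"])
        ]
    return per_motif


def perturbation_grid(
    begin: Structure,
    end: Structure,
    amap: AlignmentMap | None,
    specs: list[PerturbationSpec],
    motifs: list[MotifDefinition],
    settings: SolverSettings = SolverSettings(),
    **well_kwargs,
) -> pd.DataFrame:
    """Motif × perturbation grid of mean f_cross: the unperturbed column
    ("none") followed by one column per perturbation."""
    dw = make_double_well(begin, end, amap, **well_kwargs)
    pathway = solve_pathway(dw, settings)
    table = progress_analysis.progress_table(pathway, begin)
    baseline = progress_analysis.motif_mean(table, motifs, begin)
    grid = baseline[["motif"]].copy()
    grid["none"] = baseline["mean_f_cross"].to_numpy()
    for spec in specs:
        per = perturbed_progress(
            begin, end, amap, spec, motifs, settings, baseline=baseline, **well_kwargs
        )
        grid[spec.name] = per["mean_f_cross"].to_numpy()
    return grid
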