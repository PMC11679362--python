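"""Per-protein degradation amounts from mapped peptide intensities.

The degraded amount of a protein in one condition is the weighted sum of
its mapped peptide intensities: more fragment signal means more proteolytic
breakdown of that parent. Under the split-weight mapping policy the sum over
proteins conserves the total mapped peptide intensity exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from .mapping import LocatedPeptide
from .terminome import AggMethod, aggregate_condition_intensity


@dataclass
class ProteinDegradationProfile:
    """Degraded amounts of one protein across conditions."""

    protein_id: str
    amounts: dict[str, float]
    n_peptides: int
    n_weighted: float

    @property
    def max_amount(self) -> float:
        return max(self.amounts.values())


def protein_abundance(
    located_peptides: Iterable[LocatedPeptide],
    condition: str,
    aggregate: AggMethod = "mean",
) -> dict[str, float]:
    """Sum weight x aggregated intensity per protein for one condition.

    Proteins with no mapped peptides are absent from the result.
    """
    amounts: dict[str, float] = {}
    for lp in located_peptides:
        contrib = lp.weight * aggregate_condition_intensity(
            lp.peptide, condition, aggregate
        )
        amounts[lp.protein_id] = amounts.get(lp.protein_id, 0.0) + contrib
    return amounts


def degradation_table(
    located_peptides: Sequence[LocatedPeptide],
    conditions: Sequence[str],
    aggregate: AggMethod = "mean",
    normalize_total: bool = False,
) -> list[ProteinDegradationProfile]:
    """One degradation profile per protein, sorted by peak amount.

    Sorting is by the maximum amount over conditions, descending, with
    deterministic ties broken by protein id. ``normalize_total`` divides
    each condition's amounts by that condition's total mapped intensity
    (for runs whose injections are not comparable); off by default since
    label-free DIA replicates of one sample need no loading control.
    """
    if not conditions:
        raise ValueError("at least one condition required")
    per_cond = {c: protein_abundance(located_peptides, c, aggregate) for c in conditions}
    if normalize_total:
        for c, amounts in per_cond.items():
            total = sum(amounts.values())
            if total > 0:
                per_cond[c] = {p: v / total for p, v in amounts.items()}

    stats: dict[str, tuple[set[int], float]] = {}
    pep_ids: dict[str, set[int]] = {}
    weights: dict[str, float] = {}
    for lp in located_peptides:
        pep_ids.setdefault(lp.protein_id, set()).add(id(lp.peptide))
        weights[lp.protein_id] = weights.get(lp.protein_id, 0.0) + lp.weight

    profiles = [
        ProteinDegradationProfile(
            protein_id=pid,
            amounts={c: per_cond[c].get(pid, 0.0) for c in conditions},
            n_peptides=len(pep_ids[pid]),
            n_weighted=weights[pid],
        )
        for pid in pep_ids
    ]
    profiles.sort(key=lambda p: (-p.max_amount, p.protein_id))
    return profiles


def write_degradation_table(
    profiles: Sequence[ProteinDegradationProfile],
    conditions: Sequence[str],
    path: str | Path,
) -> None:
    """Export the degradation ranking as TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\t" + "\t".join(conditions) + "\tn_peptides\n")
        for p in profiles:
            cells = "\t".join(f"{p.amounts[c]:.12g}" for c in conditions)
            fh.write(f"{p.protein_id}\t{cells}\t{p.n_peptides}\n")


def render_degradation_bars(
    profiles: Sequence[ProteinDegradationProfile],
    conditions: Sequence[str],
    path: str | Path,
    top_n: int = 25,
) -> None:
    """Horizontal grouped-bar chart of the most degraded proteins."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt
    import numpy as np

    shown = profiles[:top_n]
    y = np.arange(len(shown))
    height = 0.8 / max(len(conditions), 1)
    fig, ax = plt.subplots(figsize=(7, max(3, 0.35 * len(shown))))
    for k, cond in enumerate(conditions):
        ax.barh(
            y + k * height,
            [p.amounts[cond] for p in shown],
            height=height,
            label=cond,
        )
    ax.set_yticks(y + 0.4 - height / 2, [p.protein_id for p in shown])
    ax.invert_yaxis()
    ax.set_xlabel("degraded amount (summed peptide intensity, a.u.)")
    ax.legend(fontsize="small")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
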