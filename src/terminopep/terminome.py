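"""Cleavage-site specificity analysis from located peptides.

Every peptide terminus that is not a native protein terminus witnesses one
scissile-bond hydrolysis. The four residues flanking that bond — the
Schechter–Berger substrate subsites P2, P1 (N-terminal side) and P1', P2'
(C-terminal side) — fingerprint the protease(s) responsible. Pooling events
per condition into a residue x subsite matrix yields the specificity
heatmap; contrasting two conditions ranks the residue/subsite cells whose
usage changed most.

Cut positions use the same convention as mapping coordinates: cut ``c``
denotes the bond between residues ``c - 1`` and ``c`` (0-based), so
P1 = protein[c-1] and P1' = protein[c].
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np

from .constants import (
    AA_INDEX,
    AMBIGUOUS,
    AMINO_ACIDS,
    N_RESIDUES,
    N_SUBSITES,
    SUBSITE_INDEX,
    SUBSITES,
)
from .io_formats import PeptideQuantRecord, ProteinRecord
from .mapping import LocatedPeptide

Weighting = Literal["count", "intensity"]
Normalization = Literal["frequency", "enrichment"]
AggMethod = Literal["mean", "median", "sum"]


@dataclass(frozen=True)
class CleavageEvent:
    """One inferred scissile-bond hydrolysis with its P2-P2' window.

    ``cut_position`` is the bond index ``c`` (bond between residues c-1 and
    c); ``terminus_side`` records which peptide terminus generated the event
    ("N" or "C"); ``weight`` is mapping-weight x condition intensity (or 1
    under count weighting downstream). Events with incomplete windows are
    never constructed.
    """

    protein_id: str
    cut_position: int
    terminus_side: str
    residues: Mapping[str, str]
    weight: float

    def __post_init__(self) -> None:
        missing = set(SUBSITES) - set(self.residues)
        if missing:
            raise ValueError(f"incomplete subsite window: missing {sorted(missing)}")
        if self.weight < 0:
            raise ValueError("event weight must be non-negative")


@dataclass
class SpecificityMatrix:
    """Residues x subsites cleavage-specificity table for one condition.

    ``values`` is 20 x 4 with rows in fixed alphabetical residue order and
    columns P2, P1, P1', P2'. In ``frequency`` mode each column is a
    probability distribution over residues (sums to 1 when events exist);
    ``enrichment`` divides those frequencies by the background residue
    composition of the parent proteins.
    """

    condition: str
    values: np.ndarray
    weighting: str = "intensity"
    normalization: str = "frequency"
    n_events: int = 0
    total_weight: float = 0.0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (N_RESIDUES, N_SUBSITES):
            raise ValueError(f"matrix must be {N_RESIDUES}x{N_SUBSITES}")

    def cell(self, residue: str, subsite: str) -> float:
        return float(self.values[AA_INDEX[residue], SUBSITE_INDEX[subsite]])

    def column(self, subsite: str) -> np.ndarray:
        return self.values[:, SUBSITE_INDEX[subsite]]


def aggregate_condition_intensity(
    record: PeptideQuantRecord, condition: str, method: AggMethod = "mean"
) -> float:
    """Collapse the replicate injections of one condition to a scalar."""
    if condition not in record.intensities:
        raise KeyError(
            f"condition {condition!r} missing from peptide {record.sequence!r}"
        )
    reps = np.asarray(record.intensities[condition], dtype=float)
    if method == "mean":
        return float(reps.mean())
    if method == "median":
        return float(np.median(reps))
    if method == "sum":
        return float(reps.sum())
    raise ValueError(f"unknown aggregation method {method!r}")


def _window(seq: str, c: int) -> dict[str, str] | None:
    """P2-P2' residues around bond c, or None if incomplete or ambiguous."""
    if c < 2 or c > len(seq) - 2:
        return None
    res = {
        "P2": seq[c - 2],
        "P1": seq[c - 1],
        "P1'": seq[c],
        "P2'": seq[c + 1],
    }
    if AMBIGUOUS in res.values():
        return None
    return res


def extract_cleavage_events(
    located_peptides: Iterable[LocatedPeptide],
    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord],
    condition: str,
    aggregate: AggMethod = "mean",
    exclude_met_excision: bool = False,
    drop_undetected: bool = True,
) -> list[CleavageEvent]:
    """Turn located peptides into per-terminus cleavage events for a condition.

    Each located peptide at ``[s, e)`` yields an N-side event at cut ``s``
    and a C-side event at cut ``e``, weighted by mapping-weight x
    replicate-aggregated intensity. Events are skipped when the cut is a
    native protein terminus, when the P2-P2' window would run past either
    protein end, when the window contains ``X``, or — with
    ``exclude_met_excision`` — when ``s`` is 1 or 2 (initiator-Met
    processing is not a proteolytic cleavage of interest). By default a
    peptide with zero aggregated intensity in this condition (not detected)
    yields no events, so ``n_events`` and count weighting reflect only
    cleavages with evidence in the condition.
    """
    if not isinstance(proteins, Mapping):
        proteins = {p.id: p for p in proteins}
    events: list[CleavageEvent] = []
    for lp in located_peptides:
        seq = proteins[lp.protein_id].sequence
        intensity = aggregate_condition_intensity(lp.peptide, condition, aggregate)
        if drop_undetected and intensity <= 0:
            continue
        w = lp.weight * intensity
        # N-terminal side: the cut that released the peptide's N terminus
        s = lp.start
        if s != 0 and not (exclude_met_excision and s in (1, 2)):
            win = _window(seq, s)
            if win is not None:
                events.append(
                    CleavageEvent(lp.protein_id, s, "N", win, w)
                )
        # C-terminal side
        e = lp.end
        if e != len(seq):
            win = _window(seq, e)
            if win is not None:
                events.append(
                    CleavageEvent(lp.protein_id, e, "C", win, w)
                )
    return events


def dedupe_cut_sites(events: Iterable[CleavageEvent]) -> list[CleavageEvent]:
    """Collapse events sharing (protein, cut position), summing weights.

    By default each peptide is independent evidence of a cleavage and events
    are kept separate; this helper implements the alternative convention.
    """
    merged: dict[tuple[str, int], CleavageEvent] = {}
    for ev in events:
        key = (ev.protein_id, ev.cut_position)
        if key in merged:
            old = merged[key]
            merged[key] = CleavageEvent(
                old.protein_id, old.cut_position, old.terminus_side,
                old.residues, old.weight + ev.weight,
            )
        else:
            merged[key] = ev
    return [merged[k] for k in sorted(merged)]


def background_composition(
    proteins: Sequence[ProteinRecord],
    restrict_to_ids: Iterable[str] | None = None,
) -> np.ndarray:
    """Residue frequencies of the (optionally restricted) parent proteins.

    Returns a length-20 vector summing to 1; ``X`` residues are ignored.
    """
    if restrict_to_ids is not None:
        ids = set(restrict_to_ids)
        proteins = [p for p in proteins if p.id in ids]
    counts = np.zeros(N_RESIDUES)
    for p in proteins:
        for aa in p.sequence:
            idx = AA_INDEX.get(aa)
            if idx is not None:
                counts[idx] += 1
    total = counts.sum()
    if total == 0:
        raise ValueError("no canonical residues in the selected proteins")
    return counts / total


def compute_specificity_matrix(
    events: Sequence[CleavageEvent],
    weighting: Weighting = "intensity",
    normalization: Normalization = "frequency",
    background: np.ndarray | None = None,
    condition: str = "",
) -> SpecificityMatrix:
    """Pool cleavage events into a 20 x 4 specificity matrix.

    ``intensity`` weighting sums event weights per (residue, subsite) cell;
    ``count`` weighting gives every event weight 1. ``frequency`` divides
    each column by the total weight so columns are residue distributions;
    ``enrichment`` additionally divides each row by the background frequency
    of that residue (required argument, error on a zero-background residue
    that occurs at some subsite).
    """
    if weighting not in ("count", "intensity"):
        raise ValueError(f"unknown weighting {weighting!r}")
    if normalization not in ("frequency", "enrichment"):
        raise ValueError(f"unknown normalization {normalization!r}")
    if normalization == "enrichment" and background is None:
        raise ValueError("enrichment normalization requires a background composition")

    raw = np.zeros((N_RESIDUES, N_SUBSITES))
    for ev in events:
        w = 1.0 if weighting == "count" else ev.weight
        for subsite, aa in ev.residues.items():
            raw[AA_INDEX[aa], SUBSITE_INDEX[subsite]] += w
    total = float(raw[:, 0].sum())  # every event contributes once per column

    values = raw
    if total > 0:
        values = raw / total
        if normalization == "enrichment":
            occurs = raw.sum(axis=1) > 0
            zero_bg = occurs & (np.asarray(background) <= 0)
            if zero_bg.any():
                bad = AMINO_ACIDS[int(np.flatnonzero(zero_bg)[0])]
                raise ValueError(
                    f"residue {bad!r} occurs at a subsite but has zero "
                    "background frequency"
                )
            with np.errstate(divide="ignore", invalid="ignore"):
                values = np.where(
                    np.asarray(background)[:, None] > 0,
                    values / np.asarray(background)[:, None],
                    0.0,
                )
    return SpecificityMatrix(
        condition=condition,
        values=values,
        weighting=weighting,
        normalization=normalization,
        n_events=len(events),
        total_weight=total,
    )


def per_protein_specificity(
    events: Sequence[CleavageEvent],
    protein_id: str,
    proteins: Sequence[ProteinRecord] | Mapping[str, ProteinRecord] | None = None,
    **kwargs,
) -> SpecificityMatrix:
    """Specificity matrix restricted to one parent protein's events.

    ``proteins`` (when given) defines the set of known ids so that a protein
    with zero events still yields an all-zero matrix rather than an error.
    """
    if proteins is not None:
        known = set(proteins) if isinstance(proteins, Mapping) else {
            p.id for p in proteins
        }
        if protein_id not in known:
            raise KeyError(f"unknown protein id {protein_id!r}")
    else:
        if protein_id not in {ev.protein_id for ev in events}:
            raise KeyError(f"unknown protein id {protein_id!r}")
    sub = [ev for ev in events if ev.protein_id == protein_id]
    return compute_specificity_matrix(sub, **kwargs)


def compare_conditions(
    matrix_a: SpecificityMatrix, matrix_b: SpecificityMatrix
) -> tuple[np.ndarray, list[tuple[str, str, float]]]:
    """Cellwise difference a - b plus a ranked list of (residue, subsite, delta).

    Entries are ranked by absolute delta, descending; ties break by subsite
    order (P2, P1, P1', P2') then residue alphabetically. Both matrices must
    share weighting and normalization.
    """
    if (matrix_a.weighting, matrix_a.normalization) != (
        matrix_b.weighting, matrix_b.normalization
    ):
        raise ValueError(
            "cannot compare matrices with different weighting/normalization: "
            f"{matrix_a.weighting}/{matrix_a.normalization} vs "
            f"{matrix_b.weighting}/{matrix_b.normalization}"
        )
    diff = matrix_a.values - matrix_b.values
    entries = [
        (AMINO_ACIDS[i], SUBSITES[j], float(diff[i, j]))
        for i in range(N_RESIDUES)
        for j in range(N_SUBSITES)
    ]
    entries.sort(key=lambda e: (-abs(e[2]), SUBSITE_INDEX[e[1]], e[0]))
    return diff, entries


def write_events(
    events: Sequence[CleavageEvent], path: str | Path, condition: str = ""
) -> None:
    """Export cleavage events as TSV."""
    with open(path, "w") as fh:
        fh.write("protein_id\tcut_position\tside\tP2\tP1\tP1prime\tP2prime\tweight\tcondition\n")
        for ev in events:
            p2, p1, p1p, p2p = (ev.residues[s] for s in SUBSITES)
            fh.write(
                f"{ev.protein_id}\t{ev.cut_position}\t{ev.terminus_side}\t"
                f"{p2}\t{p1}\t{p1p}\t{p2p}\t{ev.weight:.12g}\t{condition}\n"
            )


def write_comparison(
    ranked: Sequence[tuple[str, str, float]], path: str | Path,
    label_a: str = "a", label_b: str = "b",
) -> None:
    """Export a ranked condition contrast as TSV."""
    with open(path, "w") as fh:
        fh.write(f"# delta = {label_a} - {label_b}\n")
        fh.write("rank\tresidue\tsubsite\tdelta\n")
        for k, (aa, subsite, delta) in enumerate(ranked, start=1):
            fh.write(f"{k}\t{aa}\t{subsite}\t{delta:.12g}\n")
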