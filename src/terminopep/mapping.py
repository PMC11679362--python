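"""Locate quantified free peptides in the parent-protein collection.

Each peptide is an endogenous proteolytic fragment, so its occurrences in
the reference proteins define candidate cleavage coordinates. Peptides
shared between near-identical homologs (a real concern for salmonid
references, which carry many paralogs) are handled by an explicit
multi-mapping policy rather than silently dropped.

Coordinates are 0-based half-open ``[start, end)`` everywhere internally;
human-readable exports state their convention in the header.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Literal, Sequence

from .io_formats import PeptideQuantRecord, ProteinRecord

logger = logging.getLogger(__name__)

MatchMode = Literal["exact", "IL-equivalent"]
Policy = Literal["discard_ambiguous", "split_weight", "keep_all_unit"]

# MS cannot distinguish Leu from Ile; IL-equivalent mode collapses both to 'J'
# on both sides of the comparison. 'X' in a parent never matches anything.
_IL_TABLE = str.maketrans("IL", "JJ")


@dataclass(frozen=True)
class LocatedPeptide:
    """A peptide placed at a coordinate interval in one parent protein.

    ``weight`` apportions the peptide's intensity across its ``n_sites``
    matches (weights of one peptide sum to 1 under ``split_weight``).
    """

    peptide: PeptideQuantRecord
    protein_id: str
    start: int
    end: int
    weight: float
    n_sites: int

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if not (0.0 < self.weight <= 1.0):
            raise ValueError(f"weight {self.weight} outside (0, 1]")


@dataclass
class MappingResult:
    """Outcome of mapping a peptidome: located peptides plus bookkeeping."""

    located: list[LocatedPeptide]
    unmatched: list[PeptideQuantRecord]
    discarded_ambiguous: list[PeptideQuantRecord]
    policy: str
    match_mode: str

    @property
    def n_mapped(self) -> int:
        """Number of distinct peptides with at least one retained location."""
        return len({id(lp.peptide) for lp in self.located})

    @property
    def weight_sums_valid(self) -> bool:
        """False for keep_all_unit, where per-peptide weights can exceed 1."""
        return self.policy != "keep_all_unit"


def locate_peptide(
    sequence: str,
    proteins: Sequence[ProteinRecord],
    match_mode: MatchMode = "exact",
) -> list[tuple[str, int, int]]:
    """All occurrences of ``sequence`` in ``proteins``, overlaps included.

    Returns ``(protein_id, start, end)`` tuples ordered by protein id then
    start. ``IL-equivalent`` mode treats Leu and Ile as the same residue.
    """
    if not sequence:
        raise ValueError("empty peptide sequence")
    needle = sequence.translate(_IL_TABLE) if match_mode == "IL-equivalent" else sequence
    hits: list[tuple[str, int, int]] = []
    for prot in sorted(proteins, key=lambda p: p.id):
        hay = (
            prot.sequence.translate(_IL_TABLE)
            if match_mode == "IL-equivalent"
            else prot.sequence
        )
        pos = hay.find(needle)
        while pos != -1:
            hits.append((prot.id, pos, pos + len(needle)))
            pos = hay.find(needle, pos + 1)
    return hits


def map_peptidome(
    quant_records: Iterable[PeptideQuantRecord],
    proteins: Sequence[ProteinRecord],
    policy: Policy = "split_weight",
    match_mode: MatchMode = "exact",
) -> MappingResult:
    """Map every quantified peptide onto the protein collection.

    Policies for multi-mapping peptides (``n_sites > 1``):

    * ``split_weight`` (default) — weight ``1/n_sites`` per site, conserving
      each peptide's total intensity across homologs;
    * ``discard_ambiguous`` — drop the peptide entirely;
    * ``keep_all_unit`` — weight 1 at every site (diagnostics only; breaks
      intensity conservation, flagged via ``weight_sums_valid``).
    """
    proteins = list(proteins)
    if not proteins:
        raise ValueError("empty protein collection")
    if policy not in ("discard_ambiguous", "split_weight", "keep_all_unit"):
        raise ValueError(f"unknown policy {policy!r}")

    located: list[LocatedPeptide] = []
    unmatched: list[PeptideQuantRecord] = []
    discarded: list[PeptideQuantRecord] = []
    for rec in quant_records:
        sites = locate_peptide(rec.sequence, proteins, match_mode)
        if not sites:
            unmatched.append(rec)
            continue
        n = len(sites)
        if n > 1 and policy == "discard_ambiguous":
            discarded.append(rec)
            continue
        w = 1.0 if policy == "keep_all_unit" else 1.0 / n
        for pid, s, e in sites:
            located.append(
                LocatedPeptide(
                    peptide=rec, protein_id=pid, start=s, end=e, weight=w, n_sites=n
                )
            )
    if unmatched:
        logger.info(
            "%d peptide(s) did not match any protein: %s",
            len(unmatched),
            ", ".join(r.sequence for r in unmatched[:10]),
        )
    if discarded:
        logger.info("%d ambiguous peptide(s) discarded by policy", len(discarded))
    return MappingResult(
        located=located,
        unmatched=unmatched,
        discarded_ambiguous=discarded,
        policy=policy,
        match_mode=match_mode,
    )


def write_mapping(result: MappingResult, path: str | Path) -> None:
    """Export located peptides as TSV (0-based half-open coordinates)."""
    with open(path, "w") as fh:
        fh.write(f"# policy={result.policy} match_mode={result.match_mode}\n")
        fh.write("# coordinates: 0-based half-open [start, end)\n")
        fh.write("peptide\tprotein_id\tstart\tend\tweight\tn_sites\n")
        for lp in result.located:
            fh.write(
                f"{lp.peptide.sequence}\t{lp.protein_id}\t{lp.start}\t{lp.end}"
                f"\t{lp.weight:.12g}\t{lp.n_sites}\n"
            )
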