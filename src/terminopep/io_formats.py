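"""Readers and writers for the external formats of the pipeline.

Covers parent-protein FASTA, wide/long peptide quantification tables in the
style of DIA (SWATH) label-free exports, specificity-matrix TSV, and heatmap
rendering. The identification-confidence filter applied on load mirrors the
standard practice of discarding peptides below 95% confidence.
"""

from __future__ import annotations

import logging
import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .constants import AMBIGUOUS, AMINO_ACIDS, N_SUBSITES, SUBSITES

logger = logging.getLogger(__name__)

_VALID_PROTEIN = set(AMINO_ACIDS) | {AMBIGUOUS}
_VALID_PEPTIDE = set(AMINO_ACIDS)

# wide-format intensity columns look like "SV-52_r1", "raw_r3", ...
_INTENSITY_COL = re.compile(r"^(?P<condition>.+)_r(?P<replicate>\d+)$")


@dataclass(frozen=True)
class ProteinRecord:
    """A parent protein sequence with a stable identifier."""

    id: str
    sequence: str
    description: str = ""

    def __post_init__(self) -> None:
        if not self.id:
            raise ValueError("protein id must be non-empty")
        if not self.sequence:
            raise ValueError(f"protein {self.id!r}: empty sequence")
        bad = set(self.sequence) - _VALID_PROTEIN
        if bad:
            raise ValueError(
                f"protein {self.id!r}: invalid residue(s) {sorted(bad)!r}; "
                f"allowed are the 20 canonical codes plus {AMBIGUOUS!r}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class PeptideQuantRecord:
    """One quantified free peptide with per-condition replicate intensities.

    ``intensities`` maps a condition label to the list of replicate
    intensities (arbitrary units, one per replicate injection). A zero
    intensity means the peptide was not detected in that replicate.
    """

    sequence: str
    confidence: float
    intensities: dict[str, list[float]]

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError("peptide sequence must be non-empty")
        bad = set(self.sequence) - _VALID_PEPTIDE
        if bad:
            raise ValueError(
                f"peptide {self.sequence!r}: non-canonical residue(s) {sorted(bad)!r}"
            )
        if not 0.0 <= self.confidence <= 1.0:
            raise ValueError(
                f"peptide {self.sequence!r}: confidence {self.confidence} outside [0, 1]"
            )
        if not self.intensities:
            raise ValueError(f"peptide {self.sequence!r}: no intensity data")
        for cond, reps in self.intensities.items():
            if len(reps) == 0:
                raise ValueError(
                    f"peptide {self.sequence!r}: condition {cond!r} has no replicates"
                )
            if any(v < 0 for v in reps):
                raise ValueError(
                    f"peptide {self.sequence!r}: negative intensity in {cond!r}"
                )

    @property
    def conditions(self) -> list[str]:
        return list(self.intensities)


@dataclass(frozen=True)
class ConditionSpec:
    """A named experimental condition with a report-ordering index."""

    label: str
    order: int = 0


def read_fasta(path: str | Path) -> list[ProteinRecord]:
    """Read a multi-record FASTA of parent proteins.

    Sequences are upper-cased; duplicate ids, empty sequences and residues
    outside the canonical 20 + ``X`` are hard errors.
    """
    records: list[ProteinRecord] = []
    seen: set[str] = set()
    for rec in SeqIO.parse(str(path), "fasta"):
        if rec.id in seen:
            raise ValueError(f"duplicate protein id {rec.id!r} in {path}")
        seen.add(rec.id)
        desc = rec.description
        if desc.startswith(rec.id):
            desc = desc[len(rec.id):].strip()
        records.append(
            ProteinRecord(id=rec.id, sequence=str(rec.seq).upper(), description=desc)
        )
    return records


def write_fasta(records: Iterable[ProteinRecord], path: str | Path) -> None:
    """Write protein records as unwrapped FASTA (round-trips with read_fasta)."""
    seq_records = [
        SeqRecord(Seq(r.sequence), id=r.id, description=r.description)
        for r in records
    ]
    with open(path, "w") as fh:
        writer = SeqIO.FastaIO.FastaWriter(fh, wrap=None)
        writer.write_file(seq_records)


def _sep_for(path: Path) -> str:
    return "," if path.suffix.lower() == ".csv" else "\t"


def read_peptide_quant(
    path: str | Path,
    confidence_threshold: float = 0.95,
) -> list[PeptideQuantRecord]:
    """Read a peptide quantification table and apply the confidence filter.

    Two layouts are auto-detected by column names:

    * wide — ``peptide, confidence, <condition>_r<k>, ...`` (one intensity
      column per condition/replicate pair, PeakView-export style);
    * long — ``peptide, confidence, condition, replicate, intensity``.

    Confidence given as a percentage (any value > 1) is rescaled to a
    fraction with a logged warning. Records with confidence below
    ``confidence_threshold`` are dropped (count logged). A missing intensity
    cell means "not detected in that replicate" and is read as 0.
    """
    path = Path(path)
    df = pd.read_csv(path, sep=_sep_for(path))
    for col in ("peptide", "confidence"):
        if col not in df.columns:
            raise ValueError(f"{path}: missing required column {col!r}")
    conf = pd.to_numeric(df["confidence"], errors="coerce")
    if conf.isna().any():
        bad = df.loc[conf.isna(), "peptide"].iloc[0]
        raise ValueError(f"{path}: non-numeric confidence for peptide {bad!r}")
    if conf.max() > 1.0:
        logger.warning(
            "%s: confidence appears to be percentages (max %.3g); rescaling to [0,1]",
            path, conf.max(),
        )
        conf = conf / 100.0
    df = df.assign(confidence=conf)

    long_format = {"condition", "replicate", "intensity"} <= set(df.columns)
    if long_format:
        records = _records_from_long(df, path)
    else:
        records = _records_from_wide(df, path)

    kept = [r for r in records if r.confidence >= confidence_threshold]
    n_dropped = len(records) - len(kept)
    if n_dropped:
        logger.info(
            "%s: dropped %d/%d peptides below confidence %.3g",
            path, n_dropped, len(records), confidence_threshold,
        )
    return kept


def _records_from_wide(df: pd.DataFrame, path: Path) -> list[PeptideQuantRecord]:
    cols: list[tuple[str, int, str]] = []
    for col in df.columns:
        m = _INTENSITY_COL.match(col)
        if m and col not in ("peptide", "confidence"):
            cols.append((m["condition"], int(m["replicate"]), col))
    if not cols:
        raise ValueError(
            f"{path}: no intensity columns found (expected names like 'SV-52_r1')"
        )
    cols.sort(key=lambda c: (c[0], c[1]))
    records = []
    for row_d in df.to_dict("records"):
        intensities: dict[str, list[float]] = {}
        for cond, _rep, col in cols:
            intensities.setdefault(cond, []).append(_intensity_value(row_d[col], path))
        records.append(
            PeptideQuantRecord(
                sequence=str(row_d["peptide"]).upper(),
                confidence=float(row_d["confidence"]),
                intensities=intensities,
            )
        )
    return records


def _records_from_long(df: pd.DataFrame, path: Path) -> list[PeptideQuantRecord]:
    records = []
    for (pep, conf), grp in df.groupby(["peptide", "confidence"], sort=False):
        intensities: dict[str, list[float]] = {}
        for row in grp.sort_values(["condition", "replicate"]).itertuples():
            intensities.setdefault(str(row.condition), []).append(
                _intensity_value(row.intensity, path)
            )
        records.append(
            PeptideQuantRecord(
                sequence=str(pep).upper(),
                confidence=float(conf),
                intensities=intensities,
            )
        )
    return records


def _intensity_value(val, path: Path) -> float:
    if val is None or (isinstance(val, float) and np.isnan(val)):
        return 0.0  # not detected in that replicate
    v = float(val)
    if v < 0:
        raise ValueError(f"{path}: negative intensity {v}")
    return v


def write_peptide_quant(
    records: Sequence[PeptideQuantRecord],
    path: str | Path,
    condition_order: Sequence[str] | None = None,
) -> None:
    """Write records as a wide quant table (``peptide, confidence, <cond>_r<k>``)."""
    path = Path(path)
    if condition_order is None:
        condition_order = list(records[0].intensities) if records else []
    rows = []
    for r in records:
        row: dict[str, object] = {"peptide": r.sequence, "confidence": r.confidence}
        for cond in condition_order:
            for k, v in enumerate(r.intensities[cond], start=1):
                row[f"{cond}_r{k}"] = v
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, sep=_sep_for(path), index=False, float_format="%.12g")


# --- specificity-matrix serialization ---------------------------------------

def write_specificity_matrix(matrix, path: str | Path) -> None:
    """Serialize a SpecificityMatrix as TSV (20 residue rows x 4 subsite columns).

    Metadata (condition, weighting, normalization, event counts) goes into
    ``#``-prefixed header lines so the file round-trips losslessly.
    """
    path = Path(path)
    with open(path, "w") as fh:
        fh.write(f"# condition={matrix.condition}\n")
        fh.write(f"# weighting={matrix.weighting}\n")
        fh.write(f"# normalization={matrix.normalization}\n")
        fh.write(f"# n_events={matrix.n_events}\n")
        fh.write(f"# total_weight={matrix.total_weight!r}\n")
        fh.write("residue\t" + "\t".join(SUBSITES) + "\n")
        for i, aa in enumerate(AMINO_ACIDS):
            cells = "\t".join(f"{matrix.values[i, j]:.17g}" for j in range(N_SUBSITES))
            fh.write(f"{aa}\t{cells}\n")


def read_specificity_matrix(path: str | Path):
    """Read a specificity matrix written by :func:`write_specificity_matrix`."""
    from .terminome import SpecificityMatrix  # deferred to avoid a cycle

    meta: dict[str, str] = {}
    rows: dict[str, list[float]] = {}
    with open(path) as fh:
        for line in fh:
            line = line.rstrip("\n")
            if line.startswith("#"):
                key, _, val = line[1:].strip().partition("=")
                meta[key.strip()] = val.strip()
            elif line.startswith("residue"):
                continue
            elif line:
                parts = line.split("\t")
                rows[parts[0]] = [float(x) for x in parts[1:]]
    values = np.array([rows[aa] for aa in AMINO_ACIDS])
    return SpecificityMatrix(
        condition=meta.get("condition", ""),
        values=values,
        weighting=meta.get("weighting", "intensity"),
        normalization=meta.get("normalization", "frequency"),
        n_events=int(meta.get("n_events", 0)),
        total_weight=float(meta.get("total_weight", 0.0)),
    )


def render_heatmap(matrix, path: str | Path, cmap: str = "viridis") -> None:
    """Render a 20 x 4 specificity heatmap (rows = residues, columns = P2..P2').

    In frequency mode the columns are re-normalized to sum to one before
    plotting, so the rendered image is invariant to a uniform rescaling of
    the input intensities.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    values = matrix.values.astype(float).copy()
    if matrix.normalization == "frequency":
        colsums = values.sum(axis=0)
        nonzero = colsums > 0
        values[:, nonzero] /= colsums[nonzero]

    fig, ax = plt.subplots(figsize=(3.2, 7.0))
    im = ax.imshow(values, aspect="auto", cmap=cmap)
    ax.set_xticks(range(N_SUBSITES), SUBSITES)
    ax.set_yticks(range(len(AMINO_ACIDS)), list(AMINO_ACIDS))
    ax.set_title(matrix.condition or "specificity")
    cbar = fig.colorbar(im, ax=ax)
    cbar.set_label(f"{matrix.weighting}-weighted {matrix.normalization}")
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
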