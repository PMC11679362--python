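"""Stochastic in-silico proteolysis with known ground truth.

The generator emulates the quantitative output of a DIA (SWATH) peptidomics
experiment on sous-vide-style cooked muscle: several cooking conditions,
each digested by condition-specific proteases with position-specific
subsite preferences, three replicate injections with log-normal intensity
noise, identification confidence scores, and an optional spike of decoy
rows to exercise the confidence filter.

Cleavage model: each interior peptide bond is cut independently with
probability ``efficiency x prod over P2..P2' of normalized subsite weight``
(a PSSM-like independence assumption), so the residue frequencies observed
at realized cut sites are an unbiased estimate of the generative
preferences — which is what makes downstream specificity recovery testable.
Fragments between consecutive cuts are kept when their length falls in the
configured range and their monoisotopic mass is at or below the
ultrafiltration-style cutoff (default 10 kDa).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import yaml
from pyteomics import mass as _pt_mass

from .constants import AA_INDEX, AMINO_ACIDS, N_RESIDUES, SUBSITES
from .io_formats import PeptideQuantRecord, ProteinRecord

# monoisotopic residue masses in fixed alphabetical residue order, plus water
_RESIDUE_MASS = np.array([_pt_mass.std_aa_mass[aa] for aa in AMINO_ACIDS])
_WATER = _pt_mass.calculate_mass(formula="H2O")


def peptide_mass(sequence: str) -> float:
    """Monoisotopic mass (Da) of an unmodified peptide."""
    return float(sum(_RESIDUE_MASS[AA_INDEX[aa]] for aa in sequence) + _WATER)


@dataclass
class ProteaseModel:
    """Subsite-preference model of one protease.

    ``subsite_weights`` maps each of P2, P1, P1', P2' to a length-20 vector
    of non-negative preferences (internally rescaled so the maximum is 1);
    ``efficiency`` is the cleavage probability at a maximally preferred site.
    """

    name: str
    subsite_weights: dict[str, np.ndarray]
    efficiency: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.efficiency <= 1.0:
            raise ValueError("efficiency must lie in [0, 1]")
        norm = {}
        for subsite in SUBSITES:
            w = np.asarray(self.subsite_weights.get(subsite, np.ones(N_RESIDUES)),
                           dtype=float)
            if w.shape != (N_RESIDUES,):
                raise ValueError(f"{subsite}: weight vector must have length {N_RESIDUES}")
            if (w < 0).any():
                raise ValueError(f"{subsite}: negative preference weight")
            if w.max() <= 0:
                raise ValueError(f"{subsite}: at least one positive weight required")
            norm[subsite] = w / w.max()
        self.subsite_weights = norm

    @classmethod
    def uniform(cls, name: str = "uniform", efficiency: float = 0.1) -> "ProteaseModel":
        """A protease with no subsite preference (every residue weight 1)."""
        return cls(name, {s: np.ones(N_RESIDUES) for s in SUBSITES}, efficiency)

    @classmethod
    def from_preferences(
        cls,
        name: str,
        preferences: Mapping[str, Mapping[str, float]],
        efficiency: float = 0.1,
        baseline: float = 1.0,
    ) -> "ProteaseModel":
        """Build a model from fold-preferences, e.g. ``{"P2'": {"W": 10}}``.

        Residues not listed get ``baseline`` weight; subsites not listed are
        uniform.
        """
        weights = {}
        for subsite in SUBSITES:
            w = np.full(N_RESIDUES, baseline, dtype=float)
            for aa, fold in preferences.get(subsite, {}).items():
                w[AA_INDEX[aa]] = fold
            weights[subsite] = w
        return cls(name, weights, efficiency)

    def preference_distribution(self, subsite: str) -> np.ndarray:
        """Normalized (sum-to-1) preference distribution at one subsite."""
        w = self.subsite_weights[subsite]
        return w / w.sum()


@dataclass
class DigestParams:
    """Fragment-selection and noise parameters of the simulation.

    ``max_mass`` mirrors a 10 kDa ultrafiltration cutoff on free peptides;
    ``abundance_log_sigma`` is the SD of the log-normal draw used both for
    base peptide abundances and for per-replicate injection noise. Missed
    cleavages need no separate knob — they emerge from Bernoulli sampling.
    """

    min_length: int = 5
    max_length: int = 30
    max_mass: float = 10_000.0
    abundance_log_sigma: float = 0.5
    replicates: int = 3
    decoy_fraction: float = 0.0
    per_site_mixing: bool = False
    seed: int | None = None

    def __post_init__(self) -> None:
        if not 1 <= self.min_length <= self.max_length:
            raise ValueError("need 1 <= min_length <= max_length")
        if self.max_mass <= 0:
            raise ValueError("max_mass must be positive")
        if self.replicates < 1:
            raise ValueError("need at least one replicate")
        if not 0.0 <= self.decoy_fraction < 1.0:
            raise ValueError("decoy_fraction must lie in [0, 1)")


@dataclass
class ConditionModel:
    """Protease mixture acting in one condition."""

    label: str
    models: list[ProteaseModel]
    proportions: list[float] | None = None

    def __post_init__(self) -> None:
        if not self.models:
            raise ValueError(f"condition {self.label!r}: at least one model required")
        if self.proportions is None:
            self.proportions = [1.0 / len(self.models)] * len(self.models)
        props = np.asarray(self.proportions, dtype=float)
        if len(props) != len(self.models) or (props < 0).any() or props.sum() <= 0:
            raise ValueError(f"condition {self.label!r}: invalid mixing proportions")
        self.proportions = list(props / props.sum())

    def mixture_preference(self, subsite: str) -> np.ndarray:
        """Proportion-weighted generative preference distribution at a subsite."""
        dist = np.zeros(N_RESIDUES)
        for prop, model in zip(self.proportions, self.models):
            dist += prop * model.preference_distribution(subsite)
        return dist


@dataclass(frozen=True)
class SimulatedPeptide:
    """One realized fragment with its origin and pre-noise abundance."""

    protein_id: str
    sequence: str
    start: int
    end: int
    abundance: float


@dataclass
class SimulatedTruth:
    """Ground truth of one simulated experiment, for recovery tests."""

    conditions: dict[str, ConditionModel]
    cut_sites: dict[str, dict[str, list[int]]]          # condition -> protein -> cuts
    peptides: dict[str, list[SimulatedPeptide]]         # condition -> fragments

    def to_json(self, path: str | Path) -> None:
        payload = {
            cond: {
                "proportions": cm.proportions,
                "models": [
                    {
                        "name": m.name,
                        "efficiency": m.efficiency,
                        "subsite_weights": {
                            s: m.subsite_weights[s].tolist() for s in SUBSITES
                        },
                    }
                    for m in cm.models
                ],
                "cut_sites": self.cut_sites[cond],
                "peptides": [
                    [p.protein_id, p.sequence, p.start, p.end, p.abundance]
                    for p in self.peptides[cond]
                ],
            }
            for cond, cm in self.conditions.items()
        }
        Path(path).write_text(json.dumps(payload, indent=1))


def site_probability(model: ProteaseModel, window: str) -> float:
    """Cleavage probability for a P2-P2' window (4 residues, N->C).

    Product of the normalized subsite weights times the base efficiency; a
    window containing the ambiguity code ``X`` is never cut.
    """
    if len(window) != 4:
        raise ValueError("window must supply residues at P2, P1, P1', P2'")
    p = model.efficiency
    for subsite, aa in zip(SUBSITES, window):
        idx = AA_INDEX.get(aa)
        if idx is None:
            return 0.0
        p *= model.subsite_weights[subsite][idx]
    return float(p)


def _encode(sequence: str) -> np.ndarray:
    """Residue indices with -1 for ambiguity codes."""
    return np.array([AA_INDEX.get(aa, -1) for aa in sequence], dtype=np.int64)


def _site_probability_vector(model: ProteaseModel, idx: np.ndarray) -> np.ndarray:
    """Cut probability for every interior bond c = 1..L-1 (vectorized).

    Bonds whose P2-P2' window runs past a protein end, or covers an ``X``,
    get probability 0.
    """
    L = len(idx)
    p = np.zeros(L - 1)
    if L < 4:
        return p
    c = np.arange(2, L - 1)  # full-window bonds
    tables = [np.append(model.subsite_weights[s], 0.0) for s in SUBSITES]
    # index -1 (X) selects the appended 0 weight
    p[c - 1] = (
        model.efficiency
        * tables[0][idx[c - 2]] * tables[1][idx[c - 1]]
        * tables[2][idx[c]] * tables[3][idx[c + 1]]
    )
    return p


def digest_protein(
    protein: ProteinRecord,
    models: Sequence[ProteaseModel],
    proportions: Sequence[float],
    params: DigestParams,
    rng: np.random.Generator,
) -> tuple[list[SimulatedPeptide], list[int]]:
    """One stochastic digestion realization of a single protein.

    A protease model is drawn once per protein by the mixing proportions
    (or, with ``per_site_mixing``, each bond is cut with the mixture
    probability). Returns the retained fragments and the realized cut
    positions.
    """
    if len(protein) < params.min_length:
        raise ValueError(
            f"protein {protein.id!r} shorter than min_length {params.min_length}"
        )
    idx = _encode(protein.sequence)
    if params.per_site_mixing:
        p = np.zeros(len(idx) - 1)
        for prop, model in zip(proportions, models):
            p += prop * _site_probability_vector(model, idx)
    else:
        k = int(rng.choice(len(models), p=np.asarray(proportions)))
        p = _site_probability_vector(models[k], idx)
    cuts = [int(c) for c in np.flatnonzero(rng.random(len(p)) < p) + 1]

    cum = np.concatenate([[0.0], np.cumsum(_RESIDUE_MASS[np.maximum(idx, 0)])])
    fragments: list[SimulatedPeptide] = []
    boundaries = [0] + cuts + [len(protein)]
    for s, e in zip(boundaries[:-1], boundaries[1:]):
        if not params.min_length <= e - s <= params.max_length:
            continue
        if (idx[s:e] < 0).any():  # fragments containing X are not identifiable
            continue
        if cum[e] - cum[s] + _WATER > params.max_mass:
            continue
        fragments.append(
            SimulatedPeptide(
                protein_id=protein.id,
                sequence=protein.sequence[s:e],
                start=s,
                end=e,
                abundance=float(rng.lognormal(0.0, params.abundance_log_sigma)),
            )
        )
    return fragments, cuts


def random_proteins(
    n: int,
    length: int,
    rng: np.random.Generator,
    prefix: str = "PROT",
) -> list[ProteinRecord]:
    """Random parent proteins with uniform residue composition."""
    width = len(str(n))
    return [
        ProteinRecord(
            id=f"{prefix}{i + 1:0{width}d}",
            sequence="".join(
                AMINO_ACIDS[j] for j in rng.integers(0, N_RESIDUES, size=length)
            ),
        )
        for i in range(n)
    ]


def simulate_experiment(
    proteins: Sequence[ProteinRecord],
    conditions: Sequence[ConditionModel],
    params: DigestParams,
    rng: np.random.Generator | None = None,
) -> tuple[list[PeptideQuantRecord], SimulatedTruth]:
    """Digest the proteins under every condition and emit a quant table.

    The table is the union of all conditions' fragments, one row per unique
    peptide sequence: replicate intensities are the realized abundance times
    per-replicate log-normal noise where the peptide was generated, and 0
    (not detected) elsewhere. Confidence is Uniform(0.95, 1) for true rows;
    with ``decoy_fraction > 0``, shuffled non-mapping decoy rows with
    confidence Uniform(0, 0.95) are appended.
    """
    labels = [c.label for c in conditions]
    if len(set(labels)) != len(labels):
        raise ValueError(f"condition label collision in {labels}")
    if rng is None:
        rng = np.random.default_rng(params.seed)

    cut_sites: dict[str, dict[str, list[int]]] = {}
    peptides: dict[str, list[SimulatedPeptide]] = {}
    abundance: dict[str, dict[str, float]] = {}  # condition -> sequence -> sum
    for cm in conditions:
        cut_sites[cm.label] = {}
        peptides[cm.label] = []
        abundance[cm.label] = {}
        for prot in proteins:
            frags, cuts = digest_protein(
                prot, cm.models, cm.proportions, params, rng
            )
            cut_sites[cm.label][prot.id] = [int(c) for c in cuts]
            peptides[cm.label].extend(frags)
            for f in frags:
                abundance[cm.label][f.sequence] = (
                    abundance[cm.label].get(f.sequence, 0.0) + f.abundance
                )

    all_sequences = sorted({s for per in abundance.values() for s in per})
    records: list[PeptideQuantRecord] = []
    for seq in all_sequences:
        intensities = {}
        for cm in conditions:
            base = abundance[cm.label].get(seq, 0.0)
            if base > 0:
                noise = rng.lognormal(0.0, params.abundance_log_sigma,
                                      size=params.replicates)
                intensities[cm.label] = [float(base * z) for z in noise]
            else:
                intensities[cm.label] = [0.0] * params.replicates
        records.append(
            PeptideQuantRecord(
                sequence=seq,
                confidence=float(rng.uniform(0.95, 1.0)),
                intensities=intensities,
            )
        )

    if params.decoy_fraction > 0 and all_sequences:
        n_true = len(all_sequences)
        n_decoy = int(round(params.decoy_fraction / (1 - params.decoy_fraction) * n_true))
        haystack = "|".join(p.sequence for p in proteins)
        made = 0
        attempts = 0
        while made < n_decoy and attempts < 50 * n_decoy:
            attempts += 1
            src = all_sequences[int(rng.integers(0, n_true))]
            letters = list(src)
            rng.shuffle(letters)
            decoy = "".join(letters)
            if decoy in haystack:
                continue
            intensities = {
                cm.label: [
                    float(rng.lognormal(0.0, params.abundance_log_sigma))
                    for _ in range(params.replicates)
                ]
                for cm in conditions
            }
            records.append(
                PeptideQuantRecord(
                    sequence=decoy,
                    confidence=float(rng.uniform(0.0, 0.95)),
                    intensities=intensities,
                )
            )
            made += 1

    truth = SimulatedTruth(
        conditions={c.label: c for c in conditions},
        cut_sites=cut_sites,
        peptides=peptides,
    )
    return records, truth


def load_simulation_spec(path: str | Path) -> tuple[list[ConditionModel], DigestParams]:
    """Read a YAML/JSON simulation spec.

    Layout::

        params: {min_length: 5, max_length: 30, replicates: 3, ...}
        conditions:
          - label: raw
            proportions: [1.0]
            models:
              - name: postmortem
                efficiency: 0.1
                preferences: {"P2'": {"W": 10}}
    """
    with open(path) as fh:
        spec = yaml.safe_load(fh)
    params = DigestParams(**spec.get("params", {}))
    conditions = []
    for cond in spec["conditions"]:
        models = [
            ProteaseModel.from_preferences(
                name=m.get("name", "protease"),
                preferences=m.get("preferences", {}),
                efficiency=m.get("efficiency", 0.1),
                baseline=m.get("baseline", 1.0),
            )
            for m in cond["models"]
        ]
        conditions.append(
            ConditionModel(
                label=cond["label"],
                models=models,
                proportions=cond.get("proportions"),
            )
        )
    return conditions, params
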