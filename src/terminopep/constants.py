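"""Shared alphabets and naming conventions.

Residue rows in every specificity matrix follow the fixed alphabetical
one-letter order in :data:`AMINO_ACIDS`; the ambiguity code ``X`` is accepted
in protein sequences but never appears as a matrix row. Subsites follow the
Schechter–Berger substrate nomenclature around the scissile bond:
P2–P1 | P1'–P2' (N-terminal to C-terminal).
"""

from __future__ import annotations

AMINO_ACIDS: str = "ACDEFGHIKLMNPQRSTVWY"
AA_INDEX: dict[str, int] = {aa: i for i, aa in enumerate(AMINO_ACIDS)}

#: residue ambiguity code allowed in parent proteins (matches nothing)
AMBIGUOUS: str = "X"

#: subsite column order used everywhere (reports, matrices, heatmaps)
SUBSITES: tuple[str, str, str, str] = ("P2", "P1", "P1'", "P2'")
SUBSITE_INDEX: dict[str, int] = {s: i for i, s in enumerate(SUBSITES)}

N_RESIDUES: int = len(AMINO_ACIDS)
N_SUBSITES: int = len(SUBSITES)
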