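"""Opsin spectral-tuning sites from amino-acid alignments.

Blue-opsin λmax in the Adelpha/Limenitis clade is predicted by the residue
at spectral tuning site 195: tyrosine (Y) gives a ~431 nm pigment and
phenylalanine (F) a red-shifted ~435 nm pigment (the Y195F substitution is
a ~4 nm red shift).  Site 135 also has a documented tuning effect but no
usable prediction rule, so its residue is reported without interpretation.

Alignments are read with Biopython; site numbers refer to alignment
columns through a user-overridable numbering offset (identity by default).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
from Bio import AlignIO

GAP = "-"

#: λmax classes (nm) keyed by the residue at tuning site 195
SITE195_RULE = {"Y": 431, "F": 435}

TUNING_SITES = (135, 195)


@dataclass
class AlignedProteinSet:
    """An amino-acid alignment with literature-style site numbering.

    ``numbering_offset`` maps a site number to a 0-based alignment column;
    default: site n is alignment column n (1-based), i.e. column n-1.
    """

    sequences: dict[str, str]
    numbering_offset: dict[int, int] = field(default_factory=dict)

    def __post_init__(self) -> None:
        lengths = {len(s) for s in self.sequences.values()}
        if len(lengths) > 1:
            raise ValueError("aligned sequences must all have equal length")

    @property
    def length(self) -> int:
        return len(next(iter(self.sequences.values())))

    def column(self, site: int) -> int:
        col = self.numbering_offset.get(site, site - 1)
        if not 0 <= col < self.length:
            raise KeyError(f"site {site} maps to column {col}, outside alignment of "
                           f"length {self.length}")
        return col

    @classmethod
    def from_fasta(cls, path: str | Path,
                   numbering_offset: dict[int, int] | None = None) -> "AlignedProteinSet":
        aln = AlignIO.read(str(path), "fasta")
        return cls({rec.id: str(rec.seq).upper() for rec in aln},
                   numbering_offset or {})

    def to_fasta(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for name, seq in self.sequences.items():
                fh.write(f">{name}\n{seq}\n")


def residue_at(aln: AlignedProteinSet, seq_id: str, site: int) -> str:
    """The residue of ``seq_id`` at a literature site number ('-' for a gap)."""
    if seq_id not in aln.sequences:
        raise KeyError(f"sequence {seq_id!r} not in alignment")
    return aln.sequences[seq_id][aln.column(site)]


def predict_blue_peak(residue195: str) -> int | None:
    """Blue-rhodopsin λmax class from the site-195 residue.

    Y -> 431 nm, F -> 435 nm; any other residue (or a gap) -> None
    (unknown), since the substitution data cover only those two states.
    """
    if residue195 == GAP:
        warnings.warn("gap at tuning site 195; peak class unknown", stacklevel=2)
        return None
    return SITE195_RULE.get(residue195.upper())


def tuning_report(aln: AlignedProteinSet) -> pd.DataFrame:
    """Per-sequence residues at sites 135 and 195 and the predicted peak."""
    rows = []
    for seq_id in aln.sequences:
        r135 = residue_at(aln, seq_id, 135)
        r195 = residue_at(aln, seq_id, 195)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            peak = predict_blue_peak(r195)
        rows.append({
            "sequence": seq_id,
            "residue_135": r135,
            "residue_195": r195,
            "predicted_blue_peak_nm": peak,
        })
    return pd.DataFrame(rows)


def percent_identity(aln: AlignedProteinSet, id_a: str, id_b: str) -> tuple[int, int, float]:
    """Pairwise identity over columns where both residues are non-gap.

    Returns ``(identical, compared, percent)``; columns with a gap in
    either sequence are excluded from the denominator.
    """
    for sid in (id_a, id_b):
        if sid not in aln.sequences:
            raise KeyError(f"sequence {sid!r} not in alignment")
    sa, sb = aln.sequences[id_a], aln.sequences[id_b]
    compared = identical = 0
    for ra, rb in zip(sa, sb):
        if ra == GAP or rb == GAP:
            continue
        compared += 1
        if ra == rb:
            identical += 1
    if compared == 0:
        raise ValueError(f"no comparable (gap-free) columns between {id_a!r} and {id_b!r}")
    return identical, compared, 100.0 * identical / compared
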