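"""Reference TAD-peptide isoform definitions and published compositions.

The quantified unit is the tryptic SOX2 transactivation-domain (TAD)
peptide spanning S248, S253 and T258.  The exact tryptic sequence is not
reproduced here; a synthetic stand-in 16-mer with serines/threonine at the
same relative offsets is used instead, which leaves every mass, XIC and
stoichiometry computation structurally identical.

Two compositions of total TAD signal are provided.  For the wild-type
(fSOX2-Tg) line the three reported slices are unmodified 33.2%,
GlcNAc-S248 44.1% and phospho-S253 10.9%; the remaining 11.8% is assigned
to the co-modified GlcNAc-S248 + phospho-S253 form, completing the four
main TAD populations.  For the S248A line only the phospho-S253 slice
(18.7%) is anchored; the remainder is split between unmodified (69.5%) and
GlcNAc-T258 (11.8%) as this package's own choice (see docs/methods.md).
The doubly phosphorylated peptide is below the limit of quantitation in
both lines and is not modelled.
"""

from __future__ import annotations

from typing import Mapping, Sequence

from .ptm_quant import ModifiedPeptide

__all__ = [
    "TAD_WT_SEQUENCE",
    "TAD_S248A_SEQUENCE",
    "SITE_OFFSETS",
    "WT_TAD_FRACTIONS",
    "S248A_TAD_FRACTIONS",
    "WT_TAD_RT_CENTERS",
    "S248A_TAD_RT_CENTERS",
    "tad_isoforms",
]

#: Synthetic stand-in for the TAD tryptic peptide (not the real sequence).
TAD_WT_SEQUENCE = "GPSAPQVSDLLNTAER"
TAD_S248A_SEQUENCE = "GPAAPQVSDLLNTAER"

#: 0-based offsets of the modifiable residues within the stand-in peptide.
SITE_OFFSETS = {"S248": 2, "S253": 7, "T258": 12}

#: fSOX2-Tg (wild type) composition of total TAD signal.
WT_TAD_FRACTIONS: dict[str, float] = {
    "unmodified": 0.332,
    "GlcNAc-S248": 0.441,
    "phospho-S253": 0.109,
    "GlcNAc-S248+phospho-S253": 0.118,
}

#: fS248A-Tg composition; only the phospho-S253 slice is anchored.
S248A_TAD_FRACTIONS: dict[str, float] = {
    "unmodified": 0.695,
    "GlcNAc-T258": 0.118,
    "phospho-S253": 0.187,
}

#: Default elution centers (minutes); isoforms separate chromatographically.
WT_TAD_RT_CENTERS: dict[str, float] = {
    "unmodified": 10.0,
    "GlcNAc-S248": 12.0,
    "phospho-S253": 14.0,
    "GlcNAc-S248+phospho-S253": 16.0,
}
S248A_TAD_RT_CENTERS: dict[str, float] = {
    "unmodified": 10.0,
    "GlcNAc-T258": 12.0,
    "phospho-S253": 14.0,
}

_MODS_BY_LABEL: dict[str, tuple[tuple[str, str], ...]] = {
    "unmodified": (),
    "GlcNAc-S248": (("S248", "HexNAc"),),
    "GlcNAc-T258": (("T258", "HexNAc"),),
    "phospho-S253": (("S253", "Phospho"),),
    "GlcNAc-S248+phospho-S253": (("S248", "HexNAc"), ("S253", "Phospho")),
}


def tad_isoforms(
    labels: Sequence[str] | Mapping[str, float],
    mutant: bool = False,
    charges: Sequence[int] = (2,),
) -> list[ModifiedPeptide]:
    """Build ModifiedPeptide objects for the requested TAD isoform labels.

    ``labels`` may be a fraction mapping (its keys are used).  ``mutant``
    selects the S248A stand-in sequence, on which GlcNAc-S248 forms are
    invalid.  One peptide per (label, charge) is returned.
    """
    sequence = TAD_S248A_SEQUENCE if mutant else TAD_WT_SEQUENCE
    out = []
    for label in labels:
        mods = tuple(
            (SITE_OFFSETS[site], kind) for site, kind in _MODS_BY_LABEL[label]
        )
        for z in charges:
            out.append(ModifiedPeptide(sequence, mods, charge=z, label=label))
    return out
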