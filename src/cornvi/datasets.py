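"""Reference three-season stable-set lists for set-algebra validation.

These are the per-season sets of vegetation indices that passed the
|r| >= 0.7 twice-per-season screen in the underlying three-year field study
(12 indices in 2020, 12 in 2021, 28 in 2022; union 31, 16 stable in at
least two seasons, 5 in all three).  The season-core five (LCI, MTCI,
mND705, mSR705, RIrededge), every printed pairwise-overlap list and the
2021 uniques are transcribed; the remaining names unique to 2022 are not
individually printed and are filled with representative registry indices —
the lists are therefore a partially synthetic reconstruction whose region
*counts* are exact.  Use them to exercise :func:`cornvi.screening.venn_partition`,
not as a ground-truth index catalogue.
"""

from __future__ import annotations

__all__ = ["THREE_YEAR_STABLE_SETS"]

_CORE = {"LCI", "MTCI", "RIrededge", "mSR705", "mND705"}
_ONLY_2020_2022 = {"EVI", "MCARI2", "MSAVI", "OSAVI", "RDVI", "SAVI"}
_ONLY_2021_2022 = {"CIgreen", "PBI", "reNDVI", "SR705"}
_ONLY_2020_2021 = {"RIgreen"}
_UNIQUE_2021 = {"CVI", "TGI"}
_UNIQUE_2022 = {"NDVI", "GNDVI", "DATT", "WDRVI", "VARI", "TVI", "TCARI_OSAVI",
                "ARI", "mARI", "CRIrededge", "RVI", "SR445", "MCARI"}

THREE_YEAR_STABLE_SETS: dict[int, frozenset[str]] = {
    2020: frozenset(_CORE | _ONLY_2020_2022 | _ONLY_2020_2021),
    2021: frozenset(_CORE | _ONLY_2021_2022 | _ONLY_2020_2021 | _UNIQUE_2021),
    2022: frozenset(_CORE | _ONLY_2020_2022 | _ONLY_2021_2022 | _UNIQUE_2022),
}
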