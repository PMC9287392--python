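"""Published summary statistics of a unilateral optic-atrophy case series.

These numbers parameterize the default synthetic cohort: per-group optic-nerve
diffusivity profiles (printed scale, 1e-3 mm^2/s), their standard deviations,
and the per-case peripapillary RNFL thicknesses (µm) of the six patients.
Groups are keyed ``atrophic`` (affected eye of a patient), ``non_affected``
(fellow eye of a patient) and ``control`` (healthy subject, both eyes).
"""

from __future__ import annotations

#: Group means of the four tensor-derived measures. Diffusivities are on the
#: printed clinical scale (numerically ~0.5-1.1, i.e. units of 1e-3 mm^2/s).
GROUP_MEANS: dict[str, dict[str, float]] = {
    "atrophic": {"FA": 0.136, "MD": 0.988, "AD": 1.123, "RD": 0.920},
    "non_affected": {"FA": 0.384, "MD": 0.658, "AD": 0.955, "RD": 0.510},
    "control": {"FA": 0.389, "MD": 0.687, "AD": 0.998, "RD": 0.532},
}

#: Group standard deviations of the same measures.
GROUP_SDS: dict[str, dict[str, float]] = {
    "atrophic": {"FA": 0.059, "MD": 0.247, "AD": 0.252, "RD": 0.247},
    "non_affected": {"FA": 0.048, "MD": 0.058, "AD": 0.080, "RD": 0.054},
    "control": {"FA": 0.053, "MD": 0.079, "AD": 0.094, "RD": 0.078},
}

#: Per-case RNFL thickness (µm) of the affected and fellow eyes of the six
#: patients, in case order.
RNFL_AFFECTED_UM: tuple[float, ...] = (51.0, 60.0, 37.0, 62.0, 48.0, 41.0)
RNFL_NON_AFFECTED_UM: tuple[float, ...] = (113.0, 108.0, 109.0, 105.0, 103.0, 121.0)

#: Group mean ± SD of eye-averaged RNFL thickness in the control subjects.
RNFL_CONTROL_MEAN_UM: float = 109.64
RNFL_CONTROL_SD_UM: float = 4.99

#: Cohort sizes (number of subjects per group).
N_PATIENTS: int = 6
N_CONTROLS: int = 11

#: Sex split as a 2x2 count table ((patients F, patients M),
#: (controls F, controls M)) — 33% vs 64% female.
SEX_TABLE: tuple[tuple[int, int], tuple[int, int]] = ((2, 4), (7, 4))

#: Reported squared correlation between nerve FA and RNFL thickness across
#: the patients' eyes; the phantom cohort's RNFL noise is calibrated to it.
FA_RNFL_R2: float = 0.936
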