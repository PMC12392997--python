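"""Published base-case inputs and reference outcomes of the Shandong
combined upper-GI endoscopic screening evaluation.

These are the printed inputs the model consumes as given: compliance, test
characteristics, the discount rate, per-state utilities (EQ-5D-5L derived),
per-endoscopy screening costs and per-episode treatment costs with their
ranges and PSA distributions, plus the willingness-to-pay threshold of one
per-capita GDP (¥70,653/QALY, Shandong 2019).

The gastric treatment-cost block is reconstructed from a published table
whose second cost block was mislabelled "cardia"; the mapping to the gastric
site is this package's reading (there is no other candidate for gastric
treatment costs).
"""

from __future__ import annotations

from .params import DistributionSpec, ParameterValue

CNY = "CNY"


def _tri(a, m, b):
    return DistributionSpec("triangular", (a, m, b))


def _beta(p1, p2, lo, hi):
    return DistributionSpec("beta", (p1, p2), truncation=(lo, min(hi, 1.0)))


def _gamma(shape, rate, lo, hi):
    return DistributionSpec("gamma", (shape, rate), truncation=(lo, hi))


def _pv(name, base, lo, hi, dist=None, units=""):
    return ParameterValue(name, base, lo, hi, dist or DistributionSpec("fixed"), units)


def default_test_characteristics() -> dict[str, ParameterValue]:
    return {
        "sensitivity": _pv("test.sensitivity", 0.96, 0.90, 0.99, _tri(0.90, 0.96, 0.99)),
        "specificity": _pv("test.specificity", 0.90, 0.80, 0.95, _tri(0.80, 0.90, 0.95)),
    }


def default_compliance() -> dict[str, ParameterValue]:
    return {
        "screening": _pv("compliance.screening", 0.60, 0.30, 0.80, _tri(0.30, 0.60, 0.80)),
        "follow_up": _pv("compliance.follow_up", 0.75, 0.50, 0.90, _tri(0.50, 0.75, 0.90)),
    }


def default_discount_rate() -> ParameterValue:
    return _pv("discount_rate", 0.03, 0.02, 0.05, _tri(0.02, 0.03, 0.05))


# state utilities; ranges above 1 are clamped to 1.0
_UTILITIES = [
    # name, base, low, high, distribution
    ("healthy", 1.0, 1.0, 1.0, None),
    ("post_treatment", 1.0, 1.0, 1.0, None),  # endoscopically cured: healthy-equivalent
    ("eso_mild_dysplasia", 0.944, 0.940, 1.000, _tri(0.94, 0.98, 1.00)),
    ("eso_moderate_dysplasia", 0.939, 0.930, 1.000, _tri(0.93, 0.98, 1.00)),
    ("eso_severe_dysplasia_cis", 0.921, 0.881, 0.961, _beta(0.929, 0.145, 0.881, 0.961)),
    ("eso_early", 0.889, 0.849, 0.929, _beta(0.904, 0.180, 0.849, 0.929)),
    ("eso_advanced", 0.804, 0.764, 0.844, _beta(0.838, 0.223, 0.764, 0.844)),
    ("cardia_im", 0.960, 0.920, 1.000, _beta(0.972, 0.035, 0.920, 1.000)),
    ("cardia_lgin", 0.941, 0.940, 1.000, _tri(0.94, 0.98, 1.00)),
    ("cardia_hgin", 0.927, 0.887, 0.967, _beta(0.936, 0.09, 0.887, 0.967)),
    ("cardia_early", 0.863, 0.823, 0.903, _beta(0.894, 0.221, 0.823, 0.903)),
    ("cardia_advanced", 0.724, 0.684, 0.764, _beta(0.757, 0.303, 0.684, 0.764)),
    ("gastric_cag", 0.969, 0.929, 1.000, _beta(0.972, 0.035, 0.929, 1.000)),
    ("gastric_im", 0.960, 0.920, 1.000, _beta(0.972, 0.035, 0.920, 1.000)),
    ("gastric_lgin", 0.930, 0.930, 1.000, _tri(0.93, 0.98, 1.00)),
    ("gastric_hgin", 0.922, 0.882, 0.962, _beta(0.937, 0.150, 0.882, 0.962)),
    ("gastric_early", 0.828, 0.788, 0.868, _beta(0.939, 0.139, 0.788, 0.868)),
    ("gastric_advanced", 0.773, 0.733, 0.803, _beta(0.803, 0.286, 0.733, 0.803)),
]


def default_utilities() -> dict[str, ParameterValue]:
    return {name: _pv(f"utility.{name}", base, lo, hi, dist)
            for name, base, lo, hi, dist in _UTILITIES}


# costs in CNY; screening cost is per endoscopy attended (societal components
# itemized), treatment costs are per managed case
_COSTS = [
    ("screening_direct_medical", 629.70, 503.76, 755.64, None),
    ("screening_direct_nonmedical", 13.59, 10.87, 16.31, None),
    ("screening_indirect", 7.97, 6.38, 9.56, None),
    ("screening_total", 651.36, 521.09, 781.63, _gamma(2.16, 0.003, 521.09, 781.63)),
    ("treat_esophagus_sd_cis", 21950.52, 17560.42, 26340.62, _gamma(20.43, 0.001, 17560.42, 26340.62)),
    ("treat_esophagus_early", 44891.14, 35912.91, 53869.37, _gamma(12.23, 0.0003, 35912.91, 53869.37)),
    ("treat_esophagus_advanced_clinical", 76138.39, 60910.71, 91366.07, _gamma(26.85, 0.0004, 60910.71, 91366.07)),
    ("treat_esophagus_advanced_screen", 45683.03, 36546.43, 54819.64, _gamma(17.13, 0.0004, 36546.43, 54819.64)),
    ("treat_cardia_sd_cis", 25568.31, 20454.65, 30681.97, _gamma(4.15, 0.0002, 20454.65, 30681.97)),
    ("treat_cardia_early", 35162.11, 28129.69, 42194.53, _gamma(11.04, 0.0004, 28129.69, 42194.53)),
    ("treat_cardia_advanced_clinical", 64760.92, 51808.74, 77713.10, _gamma(22.30, 0.0004, 51808.74, 77713.10)),
    ("treat_cardia_advanced_screen", 38856.55, 31085.24, 46627.86, _gamma(8.10, 0.0002, 31085.24, 46627.86)),
    ("treat_gastric_sd_cis", 26891.98, 21513.58, 32270.38, _gamma(5.45, 0.0002, 21513.58, 32270.38)),
    ("treat_gastric_early", 44221.23, 35376.98, 53065.48, _gamma(10.13, 0.0002, 35376.98, 53065.48)),
    ("treat_gastric_advanced_clinical", 67278.45, 53822.76, 80734.14, _gamma(23.85, 0.0004, 53822.76, 80734.14)),
    ("treat_gastric_advanced_screen", 40367.07, 32293.66, 48440.48, _gamma(4.41, 0.0001, 32293.66, 48440.48)),
]


def default_costs() -> dict[str, ParameterValue]:
    return {name: _pv(f"cost.{name}", base, lo, hi, dist, units=CNY)
            for name, base, lo, hi, dist in _COSTS}


# ---------------------------------------------------------------------------
# reference cost/QALY outcomes of the 100,000-person cohort: the seven
# dominant screening strategies plus the no-screening arm, as published for
# the Shandong evaluation.  Costs in CNY (published in units of 10^4).
# ---------------------------------------------------------------------------

NO_SCREENING_CODE = "no_screening"

REFERENCE_OUTCOMES: list[tuple[str, float, float]] = [
    # code, total cost (CNY), total QALYs
    (NO_SCREENING_CODE, 23_715.23e4, 2_058_777.70),
    ("y55_nf_in", 26_722.33e4, 2_061_263.81),
    ("y50_f_in", 27_933.22e4, 2_062_142.13),
    ("y45_f_i10", 35_091.79e4, 2_065_953.84),
    ("y45_f_i5", 42_462.37e4, 2_069_733.62),
    ("y40_f_i5", 46_736.51e4, 2_071_877.61),
    ("y40_nf_i2", 66_070.35e4, 2_078_187.23),
    ("y40_nf_i1", 101_430.60e4, 2_083_483.53),
]
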