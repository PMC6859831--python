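"""Published intravisit repeatability summary for an 85-eye uveitis OCTA cohort.

These are the reported Bland-Altman summaries (bias, 95% limits of
agreement, coefficient of repeatability CR, cohort mean [SD], CR/mean
ratio) for the five quantitative indices: choriocapillaris flow-void
area (6x6 mm), superficial and deep capillary plexus FAZ area and
vessel area (3x3 mm).  Areas are in mm².

They serve two purposes: internal-consistency checks of the agreement
statistics (the printed CR must equal 1.96·SD of differences, the LoA
half-width, and CR/mean must reproduce the printed ratio), and realistic
default parameters for the synthetic cohort generator.

The superficial-plexus vessel-density row is known to be internally
inconsistent as printed (LoA half-width 0.543 vs printed CR 0.561) and
is therefore excluded from exact consistency checks.
"""

from __future__ import annotations

# index -> (n, bias, loa_lower, loa_upper, p_value, CR, mean, sd, cr_over_mean)
BLAND_ALTMAN_TABLE: dict[str, dict[str, float]] = {
    "cc_flow_void": {
        "n": 50, "bias": -0.003, "loa_lower": -0.398, "loa_upper": 0.411,
        "p_value": 0.905, "cr": 0.401, "mean": 1.16, "sd": 1.88,
        "cr_over_mean": 0.346,
    },
    "scp_faz": {
        "n": 56, "bias": 0.039, "loa_lower": -0.234, "loa_upper": 0.294,
        "p_value": 0.099, "cr": 0.264, "mean": 0.412, "sd": 0.252,
        "cr_over_mean": 0.641,
    },
    "dcp_faz": {
        "n": 56, "bias": -0.019, "loa_lower": -0.395, "loa_upper": 0.355,
        "p_value": 0.605, "cr": 0.374, "mean": 0.741, "sd": 0.214,
        "cr_over_mean": 0.505,
    },
    "scp_vd": {  # internally inconsistent as printed; kept for completeness
        "n": 56, "bias": 0.035, "loa_lower": -0.508, "loa_upper": 0.577,
        "p_value": 0.365, "cr": 0.561, "mean": 2.92, "sd": 0.663,
        "cr_over_mean": 0.191,
    },
    "dcp_vd": {
        "n": 56, "bias": 0.0216, "loa_lower": -0.748, "loa_upper": 0.791,
        "p_value": 0.682, "cr": 0.769, "mean": 3.66, "sd": 0.670,
        "cr_over_mean": 0.210,
    },
}

#: rows whose printed CR, LoA and ratio are mutually consistent at 3 dp
CONSISTENT_ROWS = ("cc_flow_void", "scp_faz", "dcp_faz", "dcp_vd")
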