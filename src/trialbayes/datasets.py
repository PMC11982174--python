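"""Published subgroup summaries packaged as typed inputs.

The numbers are the printed summary statistics for the ApoE ε4 homozygote
subgroups of the two phase 3 anti-amyloid antibody trials (CDR-SB change,
treatment minus placebo), plus the overall phase 2 donanemab effect used to
centre the optimistic informed prior.  These printed values are the only
data the full reanalysis needs.
"""

from __future__ import annotations

from .meta import StudyInput
from .priors import adversarial_scale
from .summaries import TrialSubgroupSummary, se_from_ci

#: TRAILBLAZER-ALZ2 ApoE ε4 homozygotes, donanemab vs placebo
DONANEMAB = TrialSubgroupSummary(
    label="TRAILBLAZER-ALZ2", md=-0.41, se=0.30, n_a=123, n_b=97
)

#: Clarity ApoE ε4 homozygotes, lecanemab vs placebo
LECANEMAB = TrialSubgroupSummary(label="Clarity", md=0.28, se=0.31, n_a=132, n_b=136)

#: t-statistics as printed alongside the summaries (rounded from
#: less-rounded inputs than the printed MD/SE, so not exactly MD/SE)
PRINTED_T = {
    "TRAILBLAZER-ALZ2": -1.36,
    "Clarity": 0.91,
    "donanemab versus lecanemab": -1.61,
}

#: overall phase 2 donanemab effect (TRAILBLAZER-ALZ): MD with 95% CI
PHASE2_DONANEMAB_MD = -0.36
PHASE2_DONANEMAB_CI = (-0.83, 0.12)

#: printed informed-prior parameters derived from the above
ADVERSARIAL_DONANEMAB = {"location": -0.36, "scale": 0.42, "df": 3.0}
ADVERSARIAL_DIFFERENCE = {"location": -0.15, "scale": 0.745, "df": 3.0}


def subgroup_summaries() -> list[TrialSubgroupSummary]:
    """The two packaged subgroup summaries (donanemab first)."""
    return [DONANEMAB, LECANEMAB]


def meta_studies() -> list[StudyInput]:
    """The same two results as meta-analysis inputs (y, sigma)."""
    return [
        StudyInput(label=DONANEMAB.label, y=DONANEMAB.md, sigma=DONANEMAB.se),
        StudyInput(label=LECANEMAB.label, y=LECANEMAB.md, sigma=LECANEMAB.se),
    ]


def phase2_donanemab_se(df: int = 1000) -> float:
    """SE reconstructed from the phase 2 CI (prints as 0.24)."""
    lo, hi = PHASE2_DONANEMAB_CI
    return se_from_ci(lo, hi, df)


def derived_adversarial_scales() -> dict:
    """The informed-prior scales recomputed from the printed SEs."""
    return {
        "donanemab": adversarial_scale(0.24, 3),
        "difference": adversarial_scale(0.43, 3),
    }
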