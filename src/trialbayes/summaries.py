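"""Reconstruction of effect estimates from published trial summaries.

Trials report an adjusted mean difference (MD) on the endpoint scale with a
95% confidence interval and per-arm case counts.  From those, this module
rebuilds the standard error, the t-statistic T = MD/SE, the implied standard
deviation of the effect, and Cohen's d — the quantities a Bayesian
reanalysis consumes.  It also forms the "difference of effects" contrast
between two treatments, whose MD is the difference of the MDs and whose SE
adds in quadrature.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, asdict
from typing import Iterable, Optional

import pandas as pd
from scipy import stats

from .errors import InvalidInputError

#: z quantile used for 95% intervals when df > 120 (Student t ~ normal there)
Z_975 = 1.959964
_DF_NORMAL_CUTOFF = 120


@dataclass(frozen=True)
class TrialSubgroupSummary:
    """One published subgroup result: MD with a 95% CI or SE, and arm sizes.

    ``md`` is the treatment-minus-placebo adjusted mean change difference in
    endpoint units (CDR-SB points for the packaged data; negative favours
    treatment).  Exactly one of (``ci_lower``/``ci_upper``, ``se``) is
    required; both may be given.
    """

    label: str
    md: float
    n_a: int
    n_b: int
    ci_lower: Optional[float] = None
    ci_upper: Optional[float] = None
    se: Optional[float] = None

    def __post_init__(self) -> None:
        if self.n_a < 2 or self.n_b < 2:
            raise InvalidInputError(f"{self.label}: need at least 2 cases per group")
        has_ci = self.ci_lower is not None and self.ci_upper is not None
        if not has_ci and self.se is None:
            raise InvalidInputError(f"{self.label}: need a CI pair or an SE")
        if has_ci and self.ci_lower > self.ci_upper:
            raise InvalidInputError(f"{self.label}: inverted confidence interval")
        if self.se is not None and self.se < 0:
            raise InvalidInputError(f"{self.label}: negative SE")


@dataclass(frozen=True)
class EffectEstimate:
    """Reconstructed effect: MD, SE, df, t, implied SD, and Cohen's d."""

    label: str
    md: float
    se: float
    df: int
    t: float
    sd: float
    d: float
    n_a: int
    n_b: int


def se_from_ci(ci_lower: float, ci_upper: float, df: int) -> float:
    """Standard error implied by a 95% confidence interval.

    SE = |upper - lower| / (2 * t_{df, 0.975}); for df > 120 the t quantile
    is replaced by the normal quantile 1.959964 (the two agree to three
    decimals there).
    """
    if df <= 0:
        raise InvalidInputError(f"degrees of freedom must be positive, got {df}")
    if ci_upper < ci_lower:
        raise InvalidInputError(f"inverted CI: [{ci_lower}, {ci_upper}]")
    q = Z_975 if df > _DF_NORMAL_CUTOFF else stats.t.ppf(0.975, df)
    return abs(ci_upper - ci_lower) / (2.0 * q)


def combine_se(se_a: float, se_b: float) -> float:
    """SE of a difference of two independent estimates: sqrt(se_a^2 + se_b^2)."""
    if se_a < 0 or se_b < 0:
        raise InvalidInputError("standard errors must be non-negative")
    return math.hypot(se_a, se_b)


def _resolve_df(n_a: int, n_b: int, df_convention: str) -> int:
    if df_convention == "total":
        return n_a + n_b
    if df_convention == "conventional":
        return n_a + n_b - 2
    raise InvalidInputError(f"unknown df convention: {df_convention!r}")


def effect_from_summary(
    s: TrialSubgroupSummary, df_convention: str = "total"
) -> EffectEstimate:
    """Rebuild the full effect estimate from a published summary.

    ``df_convention`` is ``"total"`` (df = n_a + n_b, the convention of the
    source analysis) or ``"conventional"`` (n_a + n_b - 2); the difference is
    negligible at trial sample sizes.  The implied SD of the effect is
    ``se * sqrt(n_a*n_b/(n_a+n_b))``, so that d = md/sd and t = md/se satisfy
    t = d * sqrt(n_a*n_b/(n_a+n_b)).
    """
    df = _resolve_df(s.n_a, s.n_b, df_convention)
    se = s.se
    if se is None:
        se = se_from_ci(s.ci_lower, s.ci_upper, df)
    if se == 0:
        raise InvalidInputError(
            f"{s.label}: SE is zero, t-statistic undefined (md={s.md})"
        )
    n_eff = s.n_a * s.n_b / (s.n_a + s.n_b)
    sd = se * math.sqrt(n_eff)
    return EffectEstimate(
        label=s.label,
        md=s.md,
        se=se,
        df=df,
        t=s.md / se,
        sd=sd,
        d=s.md / sd,
        n_a=s.n_a,
        n_b=s.n_b,
    )


def difference_effect(
    a: EffectEstimate,
    b: EffectEstimate,
    label: Optional[str] = None,
    df_convention: str = "total",
) -> EffectEstimate:
    """Contrast between two treatment effects (a minus b).

    The MD is the difference of the two MDs and the SE adds in quadrature.
    Each trial's total sample acts as one "group" of the contrast, so the
    contrast's arm sizes are (a.n_a + a.n_b, b.n_a + b.n_b).
    """
    label = label if label is not None else f"{a.label} versus {b.label}"
    summary = TrialSubgroupSummary(
        label=label,
        md=a.md - b.md,
        se=combine_se(a.se, b.se),
        n_a=a.n_a + a.n_b,
        n_b=b.n_a + b.n_b,
    )
    return effect_from_summary(summary, df_convention=df_convention)


# ---------------------------------------------------------------------------
# CSV reader / table writers


def _parse_number(text) -> Optional[float]:
    if text is None:
        return None
    s = str(text).strip()
    if s == "" or s.lower() == "nan":
        return None
    # Unicode minus (U+2212) appears in copy-pasted journal tables
    return float(s.replace("−", "-"))


def read_summaries_csv(path) -> list[TrialSubgroupSummary]:
    """Read summaries from a CSV with header label,md,ci_lower,ci_upper,se,n_a,n_b."""
    frame = pd.read_csv(path, dtype=str, keep_default_na=False)
    required = {"label", "md", "n_a", "n_b"}
    missing = required - set(frame.columns)
    if missing:
        raise InvalidInputError(f"missing CSV columns: {sorted(missing)}")
    out = []
    for idx, row in frame.iterrows():
        try:
            out.append(
                TrialSubgroupSummary(
                    label=row["label"],
                    md=_parse_number(row["md"]),
                    ci_lower=_parse_number(row.get("ci_lower")),
                    ci_upper=_parse_number(row.get("ci_upper")),
                    se=_parse_number(row.get("se")),
                    n_a=int(_parse_number(row["n_a"])),
                    n_b=int(_parse_number(row["n_b"])),
                )
            )
        except (TypeError, ValueError) as exc:
            raise InvalidInputError(f"row {idx}: {exc}") from exc
    return out


def write_summaries_csv(summaries: Iterable[TrialSubgroupSummary], path) -> None:
    rows = [asdict(s) for s in summaries]
    frame = pd.DataFrame(rows, columns=["label", "md", "ci_lower", "ci_upper", "se", "n_a", "n_b"])
    frame.to_csv(path, index=False)


def estimates_table(estimates: Iterable[EffectEstimate]) -> pd.DataFrame:
    """Reconstructed estimates as a data frame (one row per comparison)."""
    rows = []
    for e in estimates:
        rows.append(
            {
                "label": e.label,
                "md": e.md,
                "se": e.se,
                "n": f"{e.n_a}/{e.n_b}",
                "t": e.t,
                "sd": e.sd,
                "cohens_d": e.d,
                "df": e.df,
            }
        )
    return pd.DataFrame(rows)


def write_estimates(estimates: Iterable[EffectEstimate], tsv_path=None, json_path=None) -> pd.DataFrame:
    """Write the reconstructed table as TSV and/or JSON; returns the frame."""
    frame = estimates_table(estimates)
    if tsv_path is not None:
        frame.to_csv(tsv_path, sep="\t", index=False)
    if json_path is not None:
        with open(json_path, "w") as fh:
            json.dump(frame.to_dict(orient="records"), fh, indent=2)
    return frame


def round_half_away(x: float, decimals: int = 2) -> float:
    """Round half away from zero, the convention of printed trial tables."""
    factor = 10.0**decimals
    return math.copysign(math.floor(abs(x) * factor + 0.5) / factor, x)
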