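"""One-invocation assembly of the full reanalysis from a study CSV.

Given subgroup summaries, a list of comparisons, and a meta-analysis block,
this writes the reconstructed estimates table, per-comparison Bayes factor
reports (default and informed priors, with robustness curves), the
meta-analysis fit with forest-plot data, and the sensitivity table.  All
outputs are deterministic, so a rerun on the same configuration is
byte-identical.
"""

from __future__ import annotations

import json
import os
from dataclasses import dataclass, field
from typing import Optional, Sequence

import yaml

from . import datasets
from .bayesfactor import (
    bf10_adversarial,
    bf10_ttest,
    classify_evidence,
    robustness_curve,
)
from .errors import InvalidInputError
from .meta import (
    StudyInput,
    bf10_meta,
    fit_nnhm,
    forest_data,
    half_normal_prior,
    jeffreys_prior,
    posterior_summary,
    predictive,
)
from .priors import cauchy_prior
from .sensitivity import default_variants, run_sensitivity_suite
from .summaries import (
    TrialSubgroupSummary,
    difference_effect,
    effect_from_summary,
    read_summaries_csv,
    round_half_away,
    write_estimates,
)


@dataclass(frozen=True)
class Comparison:
    """One Bayes factor comparison.

    ``source`` is either a summary label or a pair (a, b) meaning the
    difference-of-effects contrast a minus b.  ``t_override`` substitutes a
    published t-statistic for the recomputed MD/SE ratio.  ``adversarial``
    optionally adds an informed-prior analysis: {location, scale, df}.
    """

    name: str
    source: object
    cauchy_scale: float = 0.707
    t_override: Optional[float] = None
    adversarial: Optional[dict] = None
    robustness: bool = True


@dataclass
class AnalysisConfig:
    """Configuration of a full reanalysis run."""

    summaries: list[TrialSubgroupSummary]
    comparisons: list[Comparison] = field(default_factory=list)
    mu_prior_sd: float = 1.0
    tau_prior_family: str = "half_normal"
    tau_prior_sd: float = 0.5
    run_meta: bool = True
    run_sensitivity: bool = True
    df_convention: str = "total"
    rounding: int = 3
    out_dir: Optional[str] = None


def reproduction_config(out_dir: Optional[str] = None) -> AnalysisConfig:
    """The packaged configuration reproducing the published analysis.

    Comparisons use the published t-statistics (the values entered into the
    original evidence computation) and the printed informed-prior
    parameters.
    """
    comparisons = [
        Comparison(
            name="donanemab",
            source="TRAILBLAZER-ALZ2",
            t_override=datasets.PRINTED_T["TRAILBLAZER-ALZ2"],
            adversarial=dict(datasets.ADVERSARIAL_DONANEMAB),
        ),
        Comparison(
            name="lecanemab",
            source="Clarity",
            t_override=datasets.PRINTED_T["Clarity"],
        ),
        Comparison(
            name="difference",
            source=("TRAILBLAZER-ALZ2", "Clarity"),
            t_override=datasets.PRINTED_T["donanemab versus lecanemab"],
            adversarial=dict(datasets.ADVERSARIAL_DIFFERENCE),
        ),
    ]
    return AnalysisConfig(
        summaries=datasets.subgroup_summaries(),
        comparisons=comparisons,
        out_dir=out_dir,
    )


def load_config(path: str, out_dir: Optional[str] = None) -> AnalysisConfig:
    """Load an :class:`AnalysisConfig` from a YAML file.

    Keys: ``input`` (study CSV path, relative to the config file),
    ``comparisons`` (list with name/source/cauchy_scale/t/adversarial),
    ``meta`` (mu_prior_sd, tau_prior, tau_prior_sd), ``sensitivity`` (bool),
    ``rounding``, ``out``.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    base = os.path.dirname(os.path.abspath(path))
    if "input" not in raw:
        raise InvalidInputError("config needs an 'input' CSV path")
    csv_path = raw["input"]
    if not os.path.isabs(csv_path):
        csv_path = os.path.join(base, csv_path)
    summaries = read_summaries_csv(csv_path)
    comparisons = []
    for c in raw.get("comparisons", []):
        src = c.get("source")
        if isinstance(src, list):
            src = tuple(src)
        comparisons.append(
            Comparison(
                name=c["name"],
                source=src,
                cauchy_scale=float(c.get("cauchy_scale", 0.707)),
                t_override=c.get("t"),
                adversarial=c.get("adversarial"),
                robustness=bool(c.get("robustness", True)),
            )
        )
    meta = raw.get("meta", {})
    return AnalysisConfig(
        summaries=summaries,
        comparisons=comparisons,
        mu_prior_sd=float(meta.get("mu_prior_sd", 1.0)),
        tau_prior_family=meta.get("tau_prior", "half_normal"),
        tau_prior_sd=float(meta.get("tau_prior_sd", 0.5)),
        run_meta=bool(raw.get("run_meta", True)),
        run_sensitivity=bool(raw.get("sensitivity", True)),
        rounding=int(raw.get("rounding", 3)),
        out_dir=out_dir or raw.get("out"),
    )


def _resolve_comparison(config: AnalysisConfig, comp: Comparison):
    by_label = {s.label: s for s in config.summaries}
    if isinstance(comp.source, tuple):
        a_label, b_label = comp.source
        for lab in (a_label, b_label):
            if lab not in by_label:
                raise InvalidInputError(f"comparison {comp.name}: unknown label {lab!r}")
        a = effect_from_summary(by_label[a_label], config.df_convention)
        b = effect_from_summary(by_label[b_label], config.df_convention)
        return difference_effect(a, b, df_convention=config.df_convention)
    if comp.source not in by_label:
        raise InvalidInputError(f"comparison {comp.name}: unknown label {comp.source!r}")
    return effect_from_summary(by_label[comp.source], config.df_convention)


class _OutputTracker:
    def __init__(self, out_dir: Optional[str]):
        self.out_dir = out_dir
        self.written: list[str] = []
        if out_dir is not None:
            os.makedirs(out_dir, exist_ok=True)

    def path(self, name: str) -> Optional[str]:
        if self.out_dir is None:
            return None
        p = os.path.join(self.out_dir, name)
        self.written.append(p)
        return p

    def rollback(self) -> None:
        for p in self.written:
            if os.path.exists(p):
                os.remove(p)


def _dump_json(obj, path: Optional[str]) -> None:
    if path is not None:
        with open(path, "w") as fh:
            json.dump(obj, fh, indent=2, sort_keys=True)


def run_full_reanalysis(config: AnalysisConfig) -> dict:
    """Run reconstruction, Bayes factor tests, meta-analysis and sensitivity.

    Returns the full evidence bundle as a dict; if ``config.out_dir`` is
    set, also writes TSV/JSON outputs there (removed again if any stage
    fails, so the directory never holds a partial run).
    """
    out = _OutputTracker(config.out_dir)
    try:
        return _run(config, out)
    except Exception:
        out.rollback()
        raise


def _run(config: AnalysisConfig, out: _OutputTracker) -> dict:
    bundle: dict = {}
    estimates = [
        effect_from_summary(s, config.df_convention) for s in config.summaries
    ]
    # contrasts referenced by comparisons join the estimates table
    table_rows = list(estimates)
    for comp in config.comparisons:
        if isinstance(comp.source, tuple):
            table_rows.append(_resolve_comparison(config, comp))
    frame = write_estimates(
        table_rows, tsv_path=out.path("estimates.tsv"), json_path=out.path("estimates.json")
    )
    bundle["estimates"] = frame.to_dict(orient="records")

    bundle["comparisons"] = {}
    for comp in config.comparisons:
        est = _resolve_comparison(config, comp)
        t = comp.t_override if comp.t_override is not None else est.t
        result = bf10_ttest(
            t,
            est.n_a,
            est.n_b,
            prior=cauchy_prior(comp.cauchy_scale),
            df_convention=config.df_convention,
        )
        record = {
            "inputs": {"t": t, "n_a": est.n_a, "n_b": est.n_b, "md": est.md, "se": est.se},
            "default_prior": result.to_dict(),
            "bf10": result.bf10,
            "bf10_rounded": round_half_away(result.bf10, config.rounding),
            "category": classify_evidence(result.bf10),
        }
        if comp.adversarial is not None:
            adv = bf10_adversarial(
                t,
                est.n_a,
                est.n_b,
                location=comp.adversarial["location"],
                scale=comp.adversarial["scale"],
                df=comp.adversarial.get("df", 3.0),
                df_convention=config.df_convention,
            )
            record["adversarial"] = adv.to_dict()
            record["adversarial"]["category"] = classify_evidence(adv.bf10)
        if comp.robustness:
            curve = robustness_curve(t, est.n_a, est.n_b, df_convention=config.df_convention)
            record["robustness"] = {
                "curve": curve.to_pairs(),
                "max_bf10": curve.max_bf10,
                "argmax_scale": curve.argmax_scale,
            }
            tsv = out.path(f"robustness_{comp.name}.tsv")
            if tsv is not None:
                with open(tsv, "w") as fh:
                    fh.write("cauchy_scale\tbf10\n")
                    for r, b in curve.to_pairs():
                        fh.write(f"{r:.6g}\t{b:.6g}\n")
        _dump_json(record, out.path(f"bf_{comp.name}.json"))
        bundle["comparisons"][comp.name] = record

    if config.run_meta:
        studies = [StudyInput(s.label, s.md, effect_from_summary(s, config.df_convention).se)
                   for s in config.summaries]
        tau_prior = (
            half_normal_prior(config.tau_prior_sd)
            if config.tau_prior_family == "half_normal"
            else jeffreys_prior()
        )
        fit = fit_nnhm(studies, mu_prior_sd=config.mu_prior_sd, tau_prior=tau_prior)
        mu = posterior_summary(fit, "mu")
        tau = posterior_summary(fit, "tau")
        pred = predictive(fit)
        bf = bf10_meta(fit)
        bf_mu = bf10_meta(fit, null="mu_zero")
        meta_record = {
            "mu": mu,
            "tau": tau,
            "prediction": pred,
            "bf10": bf["bf10"],
            "bf10_rounded": round_half_away(bf["bf10"], config.rounding),
            "bf10_null": bf["null"],
            "bf10_mu_zero": bf_mu["bf10"],
            "category": classify_evidence(bf["bf10"]),
            "grid_spec": fit.grid_spec,
            "priors": {
                "mu_prior_sd": config.mu_prior_sd,
                "tau_prior": config.tau_prior_family,
                "tau_prior_sd": config.tau_prior_sd,
            },
        }
        _dump_json(meta_record, out.path("meta.json"))
        forest = forest_data(fit)
        tsv = out.path("forest.tsv")
        if tsv is not None:
            forest.to_csv(tsv, sep="\t", index=False)
        bundle["meta"] = meta_record
        bundle["forest"] = forest.to_dict(orient="records")

        if config.run_sensitivity:
            suite = run_sensitivity_suite(studies, default_variants())
            tsv = out.path("sensitivity.tsv")
            if tsv is not None:
                suite.to_csv(tsv, sep="\t", index=False)
            _dump_json(suite.to_dict(orient="records"), out.path("sensitivity.json"))
            bundle["sensitivity"] = suite.to_dict(orient="records")

    return bundle
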