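"""Experiment orchestration: counts -> profiles -> fits -> comparison report.

Each sample (an antibiotic susceptibility test on one pre-exposure
condition) contributes replicate count tables; the pipeline builds its
resistance profile, fits the Gompertz survival curve, computes the iMIC
statistic suite, and — when a control sample is designated — compares each
sample's fitted curve to the control's and reports fold changes of the
degree of heteroresistance (DoH).
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .model import (
    GompertzFit,
    IMICSummary,
    ThresholdPolicy,
    fit_gompertz,
    summarize,
)
from .profiles import CountTable, ResistanceProfile, build_profile

__all__ = [
    "SampleResult",
    "ExperimentReport",
    "run_pipeline",
    "compare_to_control",
    "fold_change_doh",
]

logger = logging.getLogger("dropast.pipeline")


@dataclass
class SampleResult:
    """Everything computed for one sample."""

    name: str
    antibiotic: str
    tables: list[CountTable]
    profile: ResistanceProfile
    fit: GompertzFit
    summary: IMICSummary
    p_value_vs_control: float | None = None
    error: str | None = None


@dataclass
class ExperimentReport:
    """Per-sample results plus DoH fold changes against the control."""

    samples: list[SampleResult]
    control: str | None
    fold_changes_doh: dict[str, float | None] = field(default_factory=dict)
    metadata: dict = field(default_factory=dict)

    def sample(self, name: str) -> SampleResult:
        for s in self.samples:
            if s.name == name:
                return s
        raise KeyError(name)


def compare_to_control(
    sample_fit: GompertzFit,
    control_fit: GompertzFit,
    c_max: float | None = None,
    n_grid: int = 50,
    method: str = "curve",
    sample_tables: list[CountTable] | None = None,
    control_tables: list[CountTable] | None = None,
) -> float:
    """p-value for the difference between a sample's and the control's fit.

    ``method='curve'`` (default): paired two-sided t-test on the two fitted
    F_R curves evaluated on a shared grid of ``n_grid`` points spanning
    [0, c_max] (c_max defaults to the smaller of the two tested maxima).
    This is a documented operational convention — it measures systematic
    separation of the fitted curves, and its p-values are not comparable
    across grid choices.  ``method='replicates'``: unpaired two-sided
    t-test on per-replicate fitted (p1, p2) pairs, pooled over both
    parameters after scaling by the control means (requires the replicate
    tables).  Identical curves return p = 1.
    """
    if method == "curve":
        if c_max is None:
            c_max = min(sample_fit.c_max_tested, control_fit.c_max_tested)
        grid = np.linspace(0.0, c_max, n_grid)
        a = sample_fit.survival(grid)
        b = control_fit.survival(grid)
        diff = a - b
        if np.allclose(diff, 0.0):
            warnings.warn("identical fitted curves; p-value 1 by convention",
                          stacklevel=2)
            return 1.0
        res = stats.ttest_rel(a, b)
        return float(res.pvalue)
    if method == "replicates":
        if not sample_tables or not control_tables:
            raise ValueError("replicate tables required for method='replicates'")
        def rep_params(tables):
            out = []
            for t in tables:
                prof = build_profile([t])
                f = fit_gompertz(prof)
                out.append((f.p1, f.p2))
            return np.array(out)
        ps = rep_params(sample_tables)
        pc = rep_params(control_tables)
        # scale both parameters by control means so they are comparable
        scale = pc.mean(axis=0)
        res = stats.ttest_ind((ps / scale).ravel(), (pc / scale).ravel())
        return float(res.pvalue)
    raise ValueError("method must be 'curve' or 'replicates'")


def fold_change_doh(report: ExperimentReport) -> dict[str, float | None]:
    """DoH fold change of every non-control sample relative to the control.

    ``None`` where either DoH is undefined.
    """
    if report.control is None:
        raise ValueError("no control sample designated")
    control_doh = report.sample(report.control).summary.doh
    out: dict[str, float | None] = {}
    for s in report.samples:
        if s.name == report.control:
            continue
        if control_doh is None or s.summary.doh is None:
            out[s.name] = None
        else:
            out[s.name] = s.summary.doh / control_doh
    return out


def run_pipeline(
    samples: dict[str, list[CountTable]],
    control: str | None = None,
    antibiotic: str = "",
    policy: ThresholdPolicy | None = None,
    profile_method: str = "average_counts",
    comparison_method: str = "curve",
    seed: int = 0,
) -> ExperimentReport:
    """Run counts -> profile -> fit -> summary for every sample.

    A stage failure in one sample is recorded on that sample (``error``)
    and does not abort the others; samples that failed carry no summary and
    are excluded from fold changes.  Deterministic for fixed inputs.
    """
    if control is not None and control not in samples:
        raise ValueError(f"control sample {control!r} not among samples")
    policy = policy or ThresholdPolicy()
    results: list[SampleResult] = []
    for name, tables in samples.items():
        try:
            profile = build_profile(tables, method=profile_method, sample=name)
            logger.info("profile: sample=%s n_replicates=%d n_conc=%d",
                        name, len(tables), len(profile.concentration))
            fit = fit_gompertz(profile)
            logger.info("fit: sample=%s p1=%.4g p2=%.4g rss=%.3g",
                        name, fit.p1, fit.p2, fit.rss)
            summary = summarize(fit, policy, raw_tables=tables)
            results.append(
                SampleResult(
                    name=name,
                    antibiotic=antibiotic,
                    tables=tables,
                    profile=profile,
                    fit=fit,
                    summary=summary,
                )
            )
        except Exception as exc:  # surface per-sample, keep going
            logger.error("sample %s failed: %s", name, exc)
            results.append(
                SampleResult(
                    name=name,
                    antibiotic=antibiotic,
                    tables=tables,
                    profile=None,  # type: ignore[arg-type]
                    fit=None,  # type: ignore[arg-type]
                    summary=None,  # type: ignore[arg-type]
                    error=f"{type(exc).__name__}: {exc}",
                )
            )

    report = ExperimentReport(
        samples=results,
        control=control,
        metadata={"seed": seed, "policy": policy.__dict__,
                  "profile_method": profile_method},
    )
    if control is not None:
        ctrl = report.sample(control)
        if ctrl.error is None:
            for s in results:
                if s.name == control or s.error is not None:
                    continue
                s.p_value_vs_control = compare_to_control(
                    s.fit,
                    ctrl.fit,
                    method=comparison_method,
                    sample_tables=s.tables,
                    control_tables=ctrl.tables,
                )
            ok = [s for s in results if s.error is None]
            report_ok = ExperimentReport(samples=ok, control=control)
            report.fold_changes_doh = fold_change_doh(report_ok)
    return report
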