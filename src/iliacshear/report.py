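"""Case-control statistics and table reproduction.

The statistics layer of the study is deliberately plain: two-sided paired
Student t tests compare the RCIV against the LCIV within each group, and
two-sided homoscedastic (pooled-variance) t tests compare the case and
control groups vessel by vessel.  No multiple-testing correction is
applied.  p-values come from the exact t cumulative distribution
(regularized incomplete beta) — at df = 6 the headline ratio comparison
lands near 8e-5, far outside any normal approximation's accuracy.

A bundled read-only fixture carries the per-patient values printed in the
study's demographic and metric tables; :func:`reproduce_paper_statistics`
recomputes every derivable summary cell from those values and checks it
against the printed one at printed precision.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from importlib import resources
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats as _sps

from .errors import CompletenessError, DomainError, IntegrityError

__all__ = [
    "StatResult",
    "GroupTable",
    "PaperFixture",
    "load_paper_fixture",
    "sample_mean_std",
    "ttest_paired",
    "ttest_pooled",
    "normalized_differences",
    "build_group_table",
    "reproduce_paper_statistics",
    "matches_printed",
]

_FIXTURE_SHA256 = "9f8e5c86561fe5f0ac36caba6a9c3c7b00b3f62c2092c3d50a4fe7a6fccf81a4"


@dataclass(frozen=True)
class StatResult:
    """t statistic, degrees of freedom and two-sided p of one comparison."""

    t_statistic: float
    degrees_of_freedom: int
    p_two_sided: float
    test_kind: str  # "paired" | "pooled_two_sample"
    degenerate: bool = False


def sample_mean_std(values):
    """Sample mean and n−1 standard deviation.

    Mirrors the Average/Std summary columns of the study tables; a single
    observation has no defined std.
    """
    x = np.asarray(values, dtype=float)
    if x.size == 0:
        raise DomainError("empty sample")
    if x.size < 2:
        raise DomainError("std undefined for n = 1")
    return float(np.mean(x)), float(np.std(x, ddof=1))


def _p_from_t(t: float, df: int) -> float:
    """Two-sided p from the exact t distribution (incomplete-beta route)."""
    return float(2.0 * _sps.t.sf(abs(t), df))


def ttest_paired(x, y) -> StatResult:
    """Two-sided paired Student t test on the differences x − y.

    All-zero differences return t = 0, p = 1 by convention.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.ndim != 1:
        raise DomainError("paired samples must be 1-D of equal length")
    n = x.size
    if n < 2:
        raise DomainError("need n >= 2 pairs")
    d = x - y
    sd = np.std(d, ddof=1)
    if sd == 0:
        if np.all(d == 0):
            return StatResult(0.0, n - 1, 1.0, "paired", degenerate=True)
        return StatResult(np.inf, n - 1, 0.0, "paired", degenerate=True)
    t = float(np.mean(d) / (sd / np.sqrt(n)))
    return StatResult(t, n - 1, _p_from_t(t, n - 1), "paired")


def ttest_pooled(x, y) -> StatResult:
    """Two-sided homoscedastic (pooled-variance) two-sample Student t test."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    n1, n2 = x.size, y.size
    if n1 < 2 or n2 < 2:
        raise DomainError("need n >= 2 per group")
    df = n1 + n2 - 2
    sp2 = ((n1 - 1) * np.var(x, ddof=1) + (n2 - 1) * np.var(y, ddof=1)) / df
    if sp2 == 0:
        if np.mean(x) == np.mean(y):
            return StatResult(0.0, df, 1.0, "pooled_two_sample", degenerate=True)
        return StatResult(np.inf, df, 0.0, "pooled_two_sample", degenerate=True)
    t = float((np.mean(x) - np.mean(y)) / np.sqrt(sp2 * (1.0 / n1 + 1.0 / n2)))
    return StatResult(t, df, _p_from_t(t, df), "pooled_two_sample")


def normalized_differences(subject_values, control_values) -> float:
    """Group-mean contrast (mean_S − mean_C)/mean_C (dimensionless)."""
    s = np.asarray(subject_values, dtype=float)
    c = np.asarray(control_values, dtype=float)
    if s.size == 0 or c.size == 0:
        raise DomainError("both groups must be non-empty")
    cm = float(np.mean(c))
    if cm == 0:
        raise DomainError("control mean is zero; normalized difference undefined")
    return float((np.mean(s) - cm) / cm)


# ---------------------------------------------------------------------------
# Printed-precision comparison helpers

def _round_like(value: float, printed: str) -> str:
    """Render ``value`` at the precision of the printed string (half-up)."""
    q = Decimal(printed)
    return str(Decimal(value).quantize(q, rounding=ROUND_HALF_UP))


def _round_sig(value: float, sig: int) -> float:
    if value == 0:
        return 0.0
    from math import floor, log10

    k = sig - 1 - floor(log10(abs(value)))
    return float(Decimal(value).scaleb(k).quantize(Decimal(1), ROUND_HALF_UP).scaleb(-k))


def matches_printed(value: float, printed: str, kind: str = "cell") -> bool:
    """True when ``value`` agrees with a printed number.

    ``kind='cell'``: rounded (half-up) to the printed decimals, the value
    reproduces the printed string exactly.  ``kind='p'``: a p-value agrees
    when it reproduces the printed string at its decimal precision, or when
    both round to the same two significant figures — printed p columns mix
    precisions (one to five decimals) and their last digit is not always
    recoverable from the printed inputs.
    """
    exact = _round_like(value, printed) == str(Decimal(printed))
    if kind == "p":
        return exact or _round_sig(value, 2) == _round_sig(float(printed), 2)
    return exact


# ---------------------------------------------------------------------------
# Fixture

class PaperFixture:
    """Read-only accessor over the bundled printed-table values."""

    def __init__(self, payload: dict):
        self._d = payload

    def per_patient(self, table: str, metric: str, group: str, vessel: Optional[str] = None):
        """Per-patient values, e.g. ``per_patient('metrics', 'mean_shear_1_s',
        'Subject', 'LCIV')`` or ``per_patient('demographics', 'age_years',
        'Control')``."""
        node = self._d[table][vessel][metric] if vessel else self._d[table][metric]
        return np.asarray(node[group], dtype=float)

    def printed(self, table: str, metric: str, vessel: Optional[str] = None) -> dict:
        node = self._d[table][vessel][metric] if vessel else self._d[table][metric]
        return node["printed"]

    @property
    def vessels(self):
        return [v for v in self._d["metrics"] if v != "ratio"]

    def metric_names(self, vessel: str):
        return list(self._d["metrics"][vessel])

    @property
    def paired_p_printed(self) -> dict:
        return self._d["paired_p_printed"]

    @property
    def headline_printed(self) -> dict:
        return self._d["headline_printed"]


def load_paper_fixture() -> PaperFixture:
    """Load and checksum-verify the bundled printed-table fixture."""
    blob = resources.files("iliacshear.data").joinpath("paper_tables.json").read_bytes()
    digest = hashlib.sha256(blob).hexdigest()
    if digest != _FIXTURE_SHA256:
        raise IntegrityError(
            f"paper_tables.json checksum mismatch: {digest} != {_FIXTURE_SHA256}"
        )
    return PaperFixture(json.loads(blob))


# ---------------------------------------------------------------------------
# Group table

@dataclass
class GroupTable:
    """Per-patient values plus group summaries and test p-values, mirroring
    the study's metric-table layout."""

    cells: pd.DataFrame  # index (vessel, metric); per-patient, avg, std, p columns
    paired_p: pd.DataFrame  # index (group, metric): RCIV-vs-LCIV paired p


def build_group_table(records: pd.DataFrame) -> GroupTable:
    """Assemble the case-control metric table from long-format records.

    ``records`` columns: patient, group, vessel, metric, value.  Requires at
    least two patients per group and a complete (vessel, metric) grid;
    missing combinations raise :class:`CompletenessError` listing the gaps.
    """
    required = {"patient", "group", "vessel", "metric", "value"}
    if not required <= set(records.columns):
        raise DomainError(f"records need columns {sorted(required)}")
    for group in ("Subject", "Control"):
        if records.loc[records.group == group, "patient"].nunique() < 2:
            raise CompletenessError(f"need >= 2 patients in group {group}")
    gaps = []
    rows = []
    pairs = sorted(set(zip(records.vessel, records.metric)))
    for vessel, metric in pairs:
            sub = records[(records.vessel == vessel) & (records.metric == metric)]
            svals = sub.loc[sub.group == "Subject"].sort_values("patient").value.to_numpy()
            cvals = sub.loc[sub.group == "Control"].sort_values("patient").value.to_numpy()
            if svals.size < 2 or cvals.size < 2:
                gaps.append((vessel, metric))
                continue
            s_avg, s_std = sample_mean_std(svals)
            c_avg, c_std = sample_mean_std(cvals)
            rows.append(
                {
                    "vessel": vessel, "metric": metric,
                    "subject_values": svals, "subject_avg": s_avg, "subject_std": s_std,
                    "control_values": cvals, "control_avg": c_avg, "control_std": c_std,
                    "p_between": ttest_pooled(svals, cvals).p_two_sided,
                }
            )
    if gaps:
        raise CompletenessError(f"missing per-patient metrics for: {gaps}")
    cells = pd.DataFrame(rows).set_index(["vessel", "metric"])

    paired_rows = []
    paired_metrics = sorted(
        {m for v, m in pairs if v == "RCIV"} & {m for v, m in pairs if v == "LCIV"}
    )
    for group in ("Subject", "Control"):
            for metric in paired_metrics:
                rx = records[
                    (records.group == group) & (records.metric == metric) & (records.vessel == "RCIV")
                ].sort_values("patient").value.to_numpy()
                lx = records[
                    (records.group == group) & (records.metric == metric) & (records.vessel == "LCIV")
                ].sort_values("patient").value.to_numpy()
                res = ttest_paired(rx, lx)
                paired_rows.append({"group": group, "metric": metric, "p_paired": res.p_two_sided})
    paired = pd.DataFrame(paired_rows).set_index(["group", "metric"]) if paired_rows else pd.DataFrame()
    return GroupTable(cells=cells, paired_p=paired)


def fixture_records(fixture: Optional[PaperFixture] = None) -> pd.DataFrame:
    """Long-format per-patient records from the bundled fixture."""
    fx = fixture or load_paper_fixture()
    rows = []
    for vessel in ("LCIV", "RCIV"):
        for metric in fx.metric_names(vessel):
            for group in ("Subject", "Control"):
                for i, v in enumerate(fx.per_patient("metrics", metric, group, vessel)):
                    rows.append(
                        {"patient": f"{group}-{i + 1}", "group": group,
                         "vessel": vessel, "metric": metric, "value": float(v)}
                    )
    return pd.DataFrame(rows)


def reproduce_paper_statistics(fixture: Optional[PaperFixture] = None) -> pd.DataFrame:
    """Recompute every printed summary derivable from per-patient values.

    Returns one row per quantity: name, computed value, printed value, and
    whether they agree at printed precision (mean/std cells exactly;
    p-value cells at two significant figures).
    """
    fx = fixture or load_paper_fixture()
    out = []

    def add(name: str, computed: float, printed: str, kind: str = "cell") -> None:
        out.append(
            {"quantity": name, "computed": computed, "printed": printed,
             "match": matches_printed(computed, printed, kind)}
        )

    # Demographic comparisons
    for metric in fx._d["demographics"]:
        s = fx.per_patient("demographics", metric, "Subject")
        c = fx.per_patient("demographics", metric, "Control")
        printed = fx.printed("demographics", metric)
        s_avg, s_std = sample_mean_std(s)
        c_avg, c_std = sample_mean_std(c)
        add(f"demographics/{metric}/subject_avg", s_avg, printed["subject_avg"])
        add(f"demographics/{metric}/subject_std", s_std, printed["subject_std"])
        add(f"demographics/{metric}/control_avg", c_avg, printed["control_avg"])
        add(f"demographics/{metric}/control_std", c_std, printed["control_std"])
        add(f"demographics/{metric}/p", ttest_pooled(s, c).p_two_sided, printed["p"], "p")

    # Metric table cells + between-group p
    for vessel in ("LCIV", "RCIV", "ratio"):
        for metric in fx.metric_names(vessel):
            s = fx.per_patient("metrics", metric, "Subject", vessel)
            c = fx.per_patient("metrics", metric, "Control", vessel)
            printed = fx.printed("metrics", metric, vessel)
            s_avg, s_std = sample_mean_std(s)
            c_avg, c_std = sample_mean_std(c)
            add(f"{vessel}/{metric}/subject_avg", s_avg, printed["subject_avg"])
            add(f"{vessel}/{metric}/subject_std", s_std, printed["subject_std"])
            add(f"{vessel}/{metric}/control_avg", c_avg, printed["control_avg"])
            add(f"{vessel}/{metric}/control_std", c_std, printed["control_std"])
            add(f"{vessel}/{metric}/p_between", ttest_pooled(s, c).p_two_sided, printed["p"], "p")

    # Within-group paired RCIV-vs-LCIV p-values quoted in the text
    for group, metrics in fx.paired_p_printed.items():
        for metric, printed_p in metrics.items():
            r = fx.per_patient("metrics", metric, group, "RCIV")
            l = fx.per_patient("metrics", metric, group, "LCIV")
            add(f"paired/{group}/{metric}/p", ttest_paired(r, l).p_two_sided, printed_p, "p")

    # Headline quantities
    s_ratio = fx.per_patient("metrics", "lciv_rciv_shear_ratio", "Subject", "ratio")
    c_ratio = fx.per_patient("metrics", "lciv_rciv_shear_ratio", "Control", "ratio")
    add("headline/ratio_of_ratios", float(np.mean(s_ratio) / np.mean(c_ratio)),
        fx.headline_printed["ratio_of_ratios"])
    add("headline/subject_lciv_mean_peak_avg",
        float(np.mean(fx.per_patient("metrics", "mean_peak_shear_1_s", "Subject", "LCIV"))),
        fx.headline_printed["subject_lciv_mean_peak_avg_1_s"])
    add("headline/control_lciv_mean_peak_avg",
        float(np.mean(fx.per_patient("metrics", "mean_peak_shear_1_s", "Control", "LCIV"))),
        fx.headline_printed["control_lciv_mean_peak_avg_1_s"])

    return pd.DataFrame(out)
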