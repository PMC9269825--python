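"""Agreement statistics for paired device/reference readings.

Implements the ISO 80601-2-61 style accuracy metric (A_RMS), bias with a
paired t test against zero, Bland-Altman limits of agreement, Pearson and
Lin concordance correlation, MAPE for heart rate, 2x2 classification at
desaturation cut-offs with Cohen's kappa, and an OLS regression of the
paired difference on subject covariates.  `build_report` assembles these
into serializable report objects for the whole sample and the standard
desaturation subsets.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import stats

LOA_MULTIPLIER = 1.96


def _paired(device: Sequence[float], reference: Sequence[float]) -> Tuple[np.ndarray, np.ndarray]:
    d = np.asarray(device, dtype=float)
    r = np.asarray(reference, dtype=float)
    if len(d) != len(r):
        raise ValueError("device and reference series must have equal length")
    if len(d) == 0:
        raise ValueError("empty series")
    return d, r


def compute_arms(device: Sequence[float], reference: Sequence[float]) -> float:
    """Root-mean-square of the paired device-minus-reference differences:
    sqrt(sum((dev - ref)^2) / n).  Captures bias and spread jointly."""
    d, r = _paired(device, reference)
    return float(np.sqrt(np.mean((d - r) ** 2)))


@dataclass(frozen=True)
class BiasResult:
    bias: float
    ci: Tuple[float, float]
    t_stat: float
    p: float
    degenerate: bool = False  # zero-variance differences


def compute_bias(
    device: Sequence[float], reference: Sequence[float], ci_level: float = 0.95
) -> BiasResult:
    """Mean difference with t-based CI and the paired t test against 0.

    Zero-variance differences make the t statistic undefined; that case
    is reported as p = 1 with ``degenerate=True`` instead of raising, so
    perfect synthetic agreement does not crash a pipeline.
    """
    d, r = _paired(device, reference)
    if len(d) < 2:
        raise ValueError("bias test requires n >= 2")
    diff = d - r
    n = len(diff)
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    se = sd / math.sqrt(n)
    tcrit = float(stats.t.ppf(0.5 + ci_level / 2.0, n - 1))
    if sd == 0:
        return BiasResult(bias, (bias, bias), math.nan, 1.0, degenerate=True)
    t_stat = bias / se
    p = 2.0 * float(stats.t.sf(abs(t_stat), n - 1))
    return BiasResult(bias, (bias - tcrit * se, bias + tcrit * se), t_stat, p)


def bland_altman(
    device: Sequence[float], reference: Sequence[float]
) -> Tuple[float, float, Tuple[float, float]]:
    """Bias, SD of the differences (n-1) and 1.96-SD limits of agreement."""
    d, r = _paired(device, reference)
    if len(d) < 2:
        raise ValueError("Bland-Altman requires n >= 2")
    diff = d - r
    bias = float(diff.mean())
    sd = float(diff.std(ddof=1))
    return bias, sd, (bias - LOA_MULTIPLIER * sd, bias + LOA_MULTIPLIER * sd)


def pearson_r(x: Sequence[float], y: Sequence[float]) -> Tuple[float, float]:
    """Product-moment correlation with two-sided p via the t transform."""
    x, y = _paired(x, y)
    if len(x) < 3:
        raise ValueError("correlation requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("correlation undefined for constant input")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def lin_ccc(
    x: Sequence[float], y: Sequence[float], ci_level: float = 0.95
) -> Tuple[float, Tuple[float, float]]:
    """Lin's concordance correlation coefficient with a Fisher-z CI.

    ccc = 2*s_xy / (s_x^2 + s_y^2 + (mean_x - mean_y)^2) with population
    (1/n) moments; the CI uses Lin's asymptotic variance on the z scale.
    """
    x, y = _paired(x, y)
    n = len(x)
    if n < 3:
        raise ValueError("concordance requires n >= 3")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("concordance undefined for constant input")
    sx2 = float(np.var(x))
    sy2 = float(np.var(y))
    sxy = float(np.mean((x - x.mean()) * (y - y.mean())))
    dmean = float(x.mean() - y.mean())
    ccc = 2.0 * sxy / (sx2 + sy2 + dmean**2)
    r = sxy / math.sqrt(sx2 * sy2)
    # Lin (1989) asymptotic variance of atanh(ccc)
    u2 = dmean**2 / math.sqrt(sx2 * sy2)
    one = 1.0 - ccc**2
    if one <= 0 or abs(r) >= 1.0:
        return ccc, (ccc, ccc)
    if abs(r) < 1e-12:  # Lin's variance degenerates; report a vacuous CI
        return ccc, (-1.0, 1.0)
    var_z = (
        (1 - r**2) * ccc**2 / (one * r**2)
        + 2 * ccc**3 * (1 - ccc) * u2 / (r * one**2)
        - ccc**4 * u2**2 / (2 * r**2 * one**2)
    ) / (n - 2)
    var_z = max(var_z, 0.0)
    z = math.atanh(max(min(ccc, 1 - 1e-15), -1 + 1e-15))
    zcrit = float(stats.norm.ppf(0.5 + ci_level / 2.0))
    half = zcrit * math.sqrt(var_z)
    return ccc, (math.tanh(z - half), math.tanh(z + half))


def mape(device_hr: Sequence[float], reference_hr: Sequence[float]) -> float:
    """Mean absolute percent error of device HR relative to reference HR."""
    d, r = _paired(device_hr, reference_hr)
    if np.any(r <= 0):
        raise ValueError("MAPE requires strictly positive reference values")
    return float(np.mean(np.abs(d - r) / r) * 100.0)


# ---------------------------------------------------------------------------
# Classification at desaturation cut-offs
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class ClassificationResult:
    """2x2 agreement at a desaturation cut-off (positive = SpO2 <= cutoff).

    Ratios with an empty denominator are reported as None (missing),
    never as zero.
    """

    cutoff: float
    tp: int
    fp: int
    fn: int
    tn: int
    sensitivity: Optional[float]
    specificity: Optional[float]
    ppv: Optional[float]
    npv: Optional[float]
    kappa: Optional[float]

    @property
    def n(self) -> int:
        return self.tp + self.fp + self.fn + self.tn


def _ratio(num: int, den: int) -> Optional[float]:
    return num / den if den > 0 else None


def cohens_kappa(tp: int, fp: int, fn: int, tn: int) -> Optional[float]:
    """Chance-corrected agreement of two binary readings from a 2x2 table."""
    n = tp + fp + fn + tn
    if n == 0:
        return None
    po = (tp + tn) / n
    pe = ((tp + fp) * (tp + fn) + (fn + tn) * (fp + tn)) / n**2
    if pe == 1.0:
        return None  # both raters constant: chance agreement saturates
    return (po - pe) / (1.0 - pe)


def classify_at_cutoff(
    device: Sequence[float], reference: Sequence[float], cutoff: float
) -> ClassificationResult:
    """Sensitivity/specificity/PPV/NPV and Cohen's kappa for detecting
    reference SpO2 <= cutoff with the device reading."""
    d, r = _paired(device, reference)
    cond = r <= cutoff
    test = d <= cutoff
    tp = int(np.sum(cond & test))
    fn = int(np.sum(cond & ~test))
    fp = int(np.sum(~cond & test))
    tn = int(np.sum(~cond & ~test))
    return ClassificationResult(
        cutoff=cutoff,
        tp=tp,
        fp=fp,
        fn=fn,
        tn=tn,
        sensitivity=_ratio(tp, tp + fn),
        specificity=_ratio(tn, tn + fp),
        ppv=_ratio(tp, tp + fp),
        npv=_ratio(tn, tn + fn),
        kappa=cohens_kappa(tp, fp, fn, tn),
    )


# ---------------------------------------------------------------------------
# Covariate regression
# ---------------------------------------------------------------------------

def regress_difference(
    pairs: pd.DataFrame,
    response: str = "spo2",
    subset_max_ref: Optional[float] = None,
) -> pd.DataFrame:
    """OLS of the paired difference on the pair average and covariates.

    Model: (dev - ref) ~ average + age + sex (reference level: females)
    + skin colour (reference level: black) + BMI, optionally restricted
    to pairs with reference SpO2 <= ``subset_max_ref``.  Returns a
    coefficient table (B, CI95, p) whose ``attrs`` carry the multiple r
    and r^2.
    """
    import statsmodels.formula.api as smf

    if response not in ("spo2", "hr"):
        raise ValueError("response must be 'spo2' or 'hr'")
    df = pairs.copy()
    if subset_max_ref is not None:
        df = df[df["spo2_ref"] <= subset_max_ref]
    if len(df) < 10:
        raise ValueError("regression requires at least 10 pairs")
    dev, ref = f"{response}_dev", f"{response}_ref"
    df = df.assign(
        diff=df[dev] - df[ref],
        average=(df[dev] + df[ref]) / 2.0,
    )
    for col in ("average", "age_years", "bmi"):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate '{col}' has zero variance")
    for col in ("sex", "skin"):
        if df[col].nunique() < 2:
            raise ValueError(f"covariate '{col}' has zero variance")
    model = smf.ols(
        "diff ~ average + age_years + C(sex, Treatment('F')) "
        "+ C(skin, Treatment('black')) + bmi",
        data=df,
    )
    res = model.fit()
    ci = res.conf_int()
    table = pd.DataFrame(
        {
            "B": res.params,
            "ci_lo": ci[0],
            "ci_hi": ci[1],
            "p": res.pvalues,
        }
    )
    table.attrs["r2"] = float(res.rsquared)
    table.attrs["r"] = float(math.sqrt(max(res.rsquared, 0.0)))
    table.attrs["n"] = int(res.nobs)
    return table


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class AgreementReport:
    """Agreement summary for one quantity over one subset of pairs."""

    n: int
    bias: float
    bias_ci95: Tuple[float, float]
    sd_diff: float
    arms: float
    loa: Tuple[float, float]
    t_stat: float
    t_p: float
    pearson_r: float
    pearson_p: float
    lin_ccc: float
    lin_ccc_ci95: Tuple[float, float]
    mape: Optional[float] = None  # heart rate only

    def to_dict(self) -> dict:
        return asdict(self)


def _agreement(device: np.ndarray, reference: np.ndarray, with_mape: bool) -> AgreementReport:
    b = compute_bias(device, reference)
    bias, sd, loa = bland_altman(device, reference)
    r, rp = pearson_r(device, reference)
    ccc, ccc_ci = lin_ccc(device, reference)
    return AgreementReport(
        n=len(device),
        bias=bias,
        bias_ci95=b.ci,
        sd_diff=sd,
        arms=compute_arms(device, reference),
        loa=loa,
        t_stat=b.t_stat,
        t_p=b.p,
        pearson_r=r,
        pearson_p=rp,
        lin_ccc=ccc,
        lin_ccc_ci95=ccc_ci,
        mape=mape(device, reference) if with_mape else None,
    )


SUBSETS = (("all", None), ("ref_le_94", 94.0), ("ref_le_90", 90.0))


@dataclass
class ValidationReport:
    """Full validation bundle: SpO2 and HR agreement per subset plus
    classification at the desaturation cut-offs."""

    spo2: Dict[str, AgreementReport] = field(default_factory=dict)
    hr: Dict[str, AgreementReport] = field(default_factory=dict)
    classification: Dict[str, ClassificationResult] = field(default_factory=dict)
    warnings: List[str] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "spo2": {k: v.to_dict() for k, v in self.spo2.items()},
            "hr": {k: v.to_dict() for k, v in self.hr.items()},
            "classification": {k: asdict(v) for k, v in self.classification.items()},
            "warnings": list(self.warnings),
        }

    def to_json(self, **kw) -> str:
        return json.dumps(self.to_dict(), **kw)

    def summary(self) -> str:
        """Human-readable tables (2 decimals for SpO2 %, 1 for bpm)."""
        lines = []
        for name, reports, dec in (("SpO2 (%)", self.spo2, 2), ("Heart rate (bpm)", self.hr, 1)):
            lines.append(name)
            lines.append(
                f"  {'subset':10s} {'n':>5s} {'bias':>7s} {'A_RMS':>7s} "
                f"{'LoA low':>8s} {'LoA high':>8s} {'r':>6s} {'CCC':>6s}"
                + ("  MAPE%" if name.startswith("Heart") else "")
            )
            for sub, rep in reports.items():
                row = (
                    f"  {sub:10s} {rep.n:5d} {rep.bias:7.{dec}f} {rep.arms:7.{dec}f} "
                    f"{rep.loa[0]:8.{dec}f} {rep.loa[1]:8.{dec}f} "
                    f"{rep.pearson_r:6.2f} {rep.lin_ccc:6.2f}"
                )
                if rep.mape is not None:
                    row += f" {rep.mape:6.2f}"
                lines.append(row)
            lines.append("")
        lines.append("Desaturation detection (positive = SpO2 <= cutoff)")
        lines.append(
            f"  {'cutoff':>6s} {'sens':>6s} {'spec':>6s} {'PPV':>6s} {'NPV':>6s} {'kappa':>6s}"
        )
        fmt = lambda v: f"{v:6.3f}" if v is not None else "    --"
        for key, c in self.classification.items():
            lines.append(
                f"  {c.cutoff:6.0f} {fmt(c.sensitivity)} {fmt(c.specificity)} "
                f"{fmt(c.ppv)} {fmt(c.npv)} {fmt(c.kappa)}"
            )
        return "\n".join(lines)


def build_report(
    pairs: pd.DataFrame, cutoffs: Sequence[float] = (94.0, 90.0)
) -> ValidationReport:
    """Assemble the validation report from a conditioned pair table.

    One SpO2 and one HR agreement report per subset (whole range,
    reference <= 94 %, reference <= 90 %), plus classification metrics at
    each cut-off on the whole sample.  Empty or degenerate subsets are
    omitted with a warning record.
    """
    report = ValidationReport()
    for sub_name, max_ref in SUBSETS:
        sel = pairs if max_ref is None else pairs[pairs["spo2_ref"] <= max_ref]
        if len(sel) < 3:
            report.warnings.append(f"subset {sub_name}: too few pairs ({len(sel)})")
            continue
        try:
            report.spo2[sub_name] = _agreement(
                sel["spo2_dev"].to_numpy(float), sel["spo2_ref"].to_numpy(float), False
            )
        except ValueError as exc:
            report.warnings.append(f"subset {sub_name} SpO2: {exc}")
        if {"hr_dev", "hr_ref"}.issubset(sel.columns):
            try:
                report.hr[sub_name] = _agreement(
                    sel["hr_dev"].to_numpy(float), sel["hr_ref"].to_numpy(float), True
                )
            except ValueError as exc:
                report.warnings.append(f"subset {sub_name} HR: {exc}")
    for cut in cutoffs:
        report.classification[f"le_{cut:.0f}"] = classify_at_cutoff(
            pairs["spo2_dev"].to_numpy(float), pairs["spo2_ref"].to_numpy(float), cut
        )
    return report
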