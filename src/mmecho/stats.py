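"""Sex-stratified genotype comparison and manual-vs-automatic agreement.

For every knockout study the per-mouse means of LVIDd, LVIDs, EF and FS
are compared between mutants and controls with a two-sided Wilcoxon
rank-sum test, separately per sex, at alpha = 0.05 and without
multiple-testing correction (a Holm option exists but is off by default,
matching the screening convention of eight raw tests per study).
Outcomes against a manual baseline are classified as validated / lost /
gained from the two significance flags alone.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .features import MouseSummary

PARAMETERS = ("lvid_d", "lvid_s", "ef", "fs")
SEXES = ("F", "M")
_ATTR = {"lvid_d": "lvid_d_mm", "lvid_s": "lvid_s_mm", "ef": "ef_pct", "fs": "fs_pct"}

EXACT_MAX_N = 12  # exact rank-sum path for n+m <= 12 and no ties


@dataclass
class StratumResult:
    p_value: float | None
    n_control: int
    n_mutant: int
    method: str = ""
    testable: bool = True

    def significant(self, alpha: float) -> bool:
        return self.testable and self.p_value is not None and self.p_value < alpha


@dataclass
class StudyResult:
    study_name: str
    alpha: float = 0.05
    strata: dict = field(default_factory=dict)  # (param, sex) -> StratumResult
    excluded_mice: list = field(default_factory=list)

    def significant(self, param: str, sex: str) -> bool:
        return self.strata[(param, sex)].significant(self.alpha)

    def p(self, param: str, sex: str) -> float | None:
        return self.strata[(param, sex)].p_value


@dataclass
class OutcomeClass:
    """Per-stratum outcome of automatic screening vs the manual baseline."""

    categories: dict = field(default_factory=dict)  # (param, sex) -> str

    def counts(self) -> dict:
        out: dict[str, int] = {}
        for cat in self.categories.values():
            out[cat] = out.get(cat, 0) + 1
        return out


@dataclass
class AgreementReport:
    per_parameter: dict = field(default_factory=dict)
    # param -> {pearson_r, pearson_p, n, diff_median, diff_mean, diff_sd,
    #           bland_altman: {bias, lo, hi}}


def ranksum_test(x, y) -> tuple[float, str]:
    """Two-sided Wilcoxon rank-sum p-value plus the method used.

    Exact enumeration when the pooled sample is small (n+m <= 12) and
    tie-free; otherwise the mid-rank normal approximation with tie and
    continuity corrections.
    """
    x = np.asarray(x, dtype=np.float64)
    y = np.asarray(y, dtype=np.float64)
    if x.size == 0 or y.size == 0:
        raise ValueError("rank-sum test needs at least one value per group")
    pooled = np.concatenate([x, y])
    no_ties = np.unique(pooled).size == pooled.size
    if x.size + y.size <= EXACT_MAX_N and no_ties:
        method = "exact"
    else:
        method = "asymptotic"
    res = sps.mannwhitneyu(
        x, y, alternative="two-sided", method=method, use_continuity=True
    )
    return float(res.pvalue), method


def compare_study(
    summaries: list[MouseSummary],
    alpha: float = 0.05,
    study_name: str = "study",
    holm: bool = False,
) -> StudyResult:
    """Rank-sum mutant-vs-control comparison per parameter per sex.

    Mice with zero retained beats are excluded and listed; a stratum
    emptied by exclusions is marked untestable rather than silently
    dropped.  The identical set of mice feeds all four parameters.
    """
    excluded = [m.mouse_id for m in summaries if m.excluded or m.n_beats == 0]
    usable = [m for m in summaries if not (m.excluded or m.n_beats == 0)]
    result = StudyResult(study_name=study_name, alpha=alpha, excluded_mice=excluded)
    for sex in SEXES:
        ctrl = [m for m in usable if m.sex == sex and m.genotype == "control"]
        mut = [m for m in usable if m.sex == sex and m.genotype == "mutant"]
        for param in PARAMETERS:
            if not ctrl or not mut:
                result.strata[(param, sex)] = StratumResult(
                    p_value=None,
                    n_control=len(ctrl),
                    n_mutant=len(mut),
                    testable=False,
                    method="untestable",
                )
                continue
            attr = _ATTR[param]
            p, method = ranksum_test(
                [getattr(m, attr) for m in ctrl], [getattr(m, attr) for m in mut]
            )
            result.strata[(param, sex)] = StratumResult(
                p_value=p, n_control=len(ctrl), n_mutant=len(mut), method=method
            )
    if holm:
        _apply_holm(result)
    return result


def _apply_holm(result: StudyResult) -> None:
    """Holm step-down adjustment over the testable strata (optional)."""
    keys = [k for k, s in result.strata.items() if s.testable]
    ps = np.array([result.strata[k].p_value for k in keys])
    order = np.argsort(ps)
    m = len(ps)
    adj = np.empty(m)
    running = 0.0
    for rank, i in enumerate(order):
        running = max(running, (m - rank) * ps[i])
        adj[i] = min(1.0, running)
    for k, a in zip(keys, adj):
        result.strata[k].p_value = float(a)
        result.strata[k].method += "+holm"


def classify_vs_manual(auto: StudyResult, manual: StudyResult) -> OutcomeClass:
    """Validated / lost / gained taxonomy from the two significance flags.

    (manual sig, auto sig) -> validated_significant; (no, no) ->
    validated_nonsignificant; (sig, no) -> lost; (no, sig) -> gained.
    """
    if set(auto.strata) != set(manual.strata):
        raise ValueError("auto and manual results cover different strata")
    out = OutcomeClass()
    for key in auto.strata:
        a = auto.significant(*key)
        m = manual.significant(*key)
        if m and a:
            cat = "validated_significant"
        elif not m and not a:
            cat = "validated_nonsignificant"
        elif m and not a:
            cat = "lost"
        else:
            cat = "gained"
        out.categories[key] = cat
    return out


def agreement_stats(auto_means: dict, manual_means: dict, parameters=("lvid_d", "lvid_s")) -> AgreementReport:
    """Pearson correlation, paired differences and Bland-Altman limits.

    ``auto_means`` / ``manual_means`` map mouse_id -> {param: value}; only
    mice present in both tables enter (at least 3 required for r).
    Differences are auto - manual; limits of agreement are
    bias +/- 1.96 * SD.
    """
    common = sorted(set(auto_means) & set(manual_means))
    report = AgreementReport()
    for param in parameters:
        a = np.array([auto_means[m][param] for m in common], dtype=np.float64)
        b = np.array([manual_means[m][param] for m in common], dtype=np.float64)
        ok = ~(np.isnan(a) | np.isnan(b))
        a, b = a[ok], b[ok]
        if a.size < 3:
            raise ValueError(f"need >= 3 mice in common for {param}, got {a.size}")
        if np.std(a) == 0 or np.std(b) == 0:
            r, rp = (1.0 if np.allclose(a - a.mean(), b - b.mean()) else float("nan")), float("nan")
        else:
            r, rp = sps.pearsonr(a, b)
        diff = a - b
        sd = float(diff.std(ddof=1)) if diff.size > 1 else 0.0
        bias = float(diff.mean())
        report.per_parameter[param] = {
            "pearson_r": float(r),
            "pearson_p": float(rp),
            "n": int(a.size),
            "diff_median": float(np.median(diff)),
            "diff_mean": bias,
            "diff_sd": sd,
            "bland_altman": {"bias": bias, "lo": bias - 1.96 * sd, "hi": bias + 1.96 * sd},
        }
    return report
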