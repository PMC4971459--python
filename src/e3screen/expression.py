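"""qPCR quantification and downstream expression calls.

Implements the comparative-Ct (delta-delta-Ct) method

    fold = 2^-((Ct_target - Ct_ref)_sample - (Ct_target - Ct_ref)_calibrator)

with replicate Ct values averaged *before* the per-sample delta-Ct
(standard practice for technical replicates), the tau tissue-specificity
index over mean fold profiles, ER-stress responsiveness calls (one-way
ANOVA across timepoints per stressor, Bonferroni-adjusted pairwise tests
against the untreated control, requiring induction under *both*
thapsigargin and tunicamycin), and the crystal-violet viability ratio.

Ct tables are long-format pandas DataFrames with columns
``sample, gene, replicate, ct`` (plus optional ``condition`` /
``time_h`` / ``tissue`` metadata carried through).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

CT_COLUMNS = ["sample", "gene", "replicate", "ct"]


def read_ct_table(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(CT_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    return df


def _check_ct_table(table: pd.DataFrame) -> None:
    missing = set(CT_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"Ct table missing column(s): {sorted(missing)}")
    if not np.isfinite(table["ct"]).all():
        raise ValueError("non-finite Ct value(s) in table")


@dataclass(frozen=True)
class FoldChange:
    """Relative expression of one gene in one sample vs the calibrator."""

    gene: str
    sample: str
    fold: float  # 2^-ddCt from per-sample mean Ct values
    replicate_folds: tuple[float, ...]
    mean: float  # mean of replicate folds
    sd: float  # sd (ddof=1) of replicate folds; 0.0 for a single replicate

    def __post_init__(self) -> None:
        if self.fold <= 0:
            raise ValueError("fold must be positive")


def delta_delta_ct(
    table: pd.DataFrame,
    target: str,
    reference: str,
    calibrator: str,
) -> dict[str, FoldChange]:
    """Comparative-Ct fold changes for ``target`` in every sample.

    Per sample, dCt = mean Ct_target − mean Ct_reference; ddCt subtracts
    the calibrator's dCt; fold = 2^−ddCt (so the calibrator's own fold is
    exactly 1).  Replicate-level folds use each target replicate against
    the sample's mean reference Ct.  Raises if the reference or target is
    missing from any sample, or the calibrator sample is absent.
    """
    _check_ct_table(table)
    samples = list(dict.fromkeys(table["sample"]))
    if calibrator not in samples:
        raise ValueError(f"calibrator sample {calibrator!r} not in table")

    ref_mean: dict[str, float] = {}
    target_cts: dict[str, np.ndarray] = {}
    for sample in samples:
        sub = table[table["sample"] == sample]
        ref = sub.loc[sub["gene"] == reference, "ct"]
        tgt = sub.loc[sub["gene"] == target, "ct"]
        if ref.empty:
            raise ValueError(f"reference gene {reference!r} missing in sample {sample!r}")
        if tgt.empty:
            raise ValueError(f"target gene {target!r} missing in sample {sample!r}")
        ref_mean[sample] = float(ref.mean())
        target_cts[sample] = tgt.to_numpy(dtype=float)

    dct_cal = float(target_cts[calibrator].mean()) - ref_mean[calibrator]

    out: dict[str, FoldChange] = {}
    for sample in samples:
        dct = float(target_cts[sample].mean()) - ref_mean[sample]
        rep_folds = tuple(
            float(2.0 ** -((ct - ref_mean[sample]) - dct_cal))
            for ct in target_cts[sample]
        )
        sd = float(np.std(rep_folds, ddof=1)) if len(rep_folds) > 1 else 0.0
        out[sample] = FoldChange(
            gene=target,
            sample=sample,
            fold=float(2.0 ** -(dct - dct_cal)),
            replicate_folds=rep_folds,
            mean=float(np.mean(rep_folds)),
            sd=sd,
        )
    return out


# ---------------------------------------------------------------------------
# Tissue specificity

SPECIFIC = "specific"
SELECTIVE = "selective"
UBIQUITOUS = "ubiquitous"


def tissue_profile(
    folds: Mapping[str, "FoldChange | float"],
    specific_threshold: float = 0.95,
    selective_threshold: float = 0.85,
) -> tuple[float, str]:
    """Tau tissue-specificity index and qualitative class.

    tau = sum(1 − x_i/x_max) / (n − 1) over per-tissue mean folds: 0 for a
    uniform profile, 1 for single-tissue expression.  Class thresholds
    (specific >= 0.95, selective >= 0.85) are descriptive defaults; there
    is no inferential claim behind them.
    """
    values = np.array(
        [f.fold if isinstance(f, FoldChange) else float(f) for f in folds.values()],
        dtype=float,
    )
    if len(values) < 5:
        raise ValueError("tissue profile requires >= 5 tissues")
    if (values < 0).any():
        raise ValueError("negative expression values")
    x_max = values.max()
    if x_max == 0:
        raise ValueError("all-zero expression profile: tau undefined")
    tau = float(np.sum(1.0 - values / x_max) / (len(values) - 1))
    if tau >= specific_threshold:
        cls = SPECIFIC
    elif tau >= selective_threshold:
        cls = SELECTIVE
    else:
        cls = UBIQUITOUS
    return tau, cls


# ---------------------------------------------------------------------------
# ER-stress responsiveness


@dataclass(frozen=True)
class ResponsivenessCall:
    """ER-stress responsiveness verdict for one gene.

    ``per_condition`` maps condition -> {time_h: (mean_fold, p_adjusted)};
    ``anova_p`` maps condition -> one-way ANOVA p across timepoint groups
    (control included).  ``responsive`` requires, under *every* tested
    stressor, ANOVA significance plus at least one timepoint with
    adjusted p < alpha and mean fold > 1.
    """

    gene: str
    per_condition: Mapping[str, Mapping[float, tuple[float, float]]]
    anova_p: Mapping[str, float]
    responsive: bool


def _anova_p(groups: Sequence[np.ndarray]) -> float:
    if len(groups) < 2:
        raise ValueError("ANOVA requires >= 2 groups")
    pooled_within_var = sum(float(np.var(g, ddof=1)) for g in groups if len(g) > 1)
    means = [float(np.mean(g)) for g in groups]
    if pooled_within_var == 0.0:
        warnings.warn(
            "zero within-group variance; ANOVA p taken as exact limit",
            RuntimeWarning,
        )
        return 1.0 if len(set(means)) == 1 else 0.0
    return float(stats.f_oneway(*groups).pvalue)


def _pairwise_p(a: np.ndarray, b: np.ndarray) -> float:
    if np.var(a, ddof=1) == 0.0 and np.var(b, ddof=1) == 0.0:
        warnings.warn(
            "zero variance in both groups; p taken as exact limit",
            RuntimeWarning,
        )
        return 1.0 if np.mean(a) == np.mean(b) else 0.0
    return float(stats.ttest_ind(a, b).pvalue)


def responsiveness(
    table: pd.DataFrame,
    genes: Sequence[str],
    reference: str,
    conditions: Sequence[str] = ("Tg", "Tm"),
    control: str = "control",
    alpha: float = 0.05,
) -> list[ResponsivenessCall]:
    """Call ER-stress responsiveness per gene from a timecourse Ct table.

    The table needs ``condition`` and ``time_h`` columns; the untreated
    control is the sample whose ``condition`` equals ``control`` and is
    shared across stressors.  Per gene and condition a one-way ANOVA runs
    over replicate delta-Ct values across timepoint groups including the
    control; pairwise t-tests of each timepoint against control are
    Bonferroni-adjusted (raw p x number of comparisons, capped at 1) and
    only count when the ANOVA itself is significant.  A gene is
    responsive iff every condition shows at least one timepoint with
    adjusted p < alpha and mean fold > 1.
    """
    _check_ct_table(table)
    for col in ("condition", "time_h"):
        if col not in table.columns:
            raise ValueError(f"responsiveness needs a {col!r} column")

    control_rows = table[table["condition"] == control]
    if control_rows.empty:
        raise ValueError(f"no control rows (condition == {control!r})")
    control_sample = str(control_rows["sample"].iloc[0])

    calls: list[ResponsivenessCall] = []
    for gene in genes:
        folds = delta_delta_ct(table, gene, reference, calibrator=control_sample)
        # replicate-level dCt per sample for the test statistics
        dct: dict[str, np.ndarray] = {}
        for sample in folds:
            sub = table[table["sample"] == sample]
            ref_mean = float(sub.loc[sub["gene"] == reference, "ct"].mean())
            dct[sample] = (
                sub.loc[sub["gene"] == gene, "ct"].to_numpy(dtype=float) - ref_mean
            )

        per_condition: dict[str, dict[float, tuple[float, float]]] = {}
        anova_p: dict[str, float] = {}
        cond_ok: dict[str, bool] = {}
        for cond in conditions:
            cond_rows = table[table["condition"] == cond]
            if cond_rows.empty:
                raise ValueError(f"no rows for condition {cond!r}")
            time_samples = (
                cond_rows[["time_h", "sample"]]
                .drop_duplicates()
                .sort_values("time_h")
            )
            groups = [dct[control_sample]] + [
                dct[str(s)] for s in time_samples["sample"]
            ]
            if any(len(g) < 3 for g in groups):
                raise ValueError(
                    f"{gene}/{cond}: every group needs >= 3 replicates"
                )
            p_anova = _anova_p(groups)
            anova_p[cond] = p_anova
            n_comp = len(time_samples)
            results: dict[float, tuple[float, float]] = {}
            any_significant = False
            for t, sample in time_samples.itertuples(index=False):
                p_raw = _pairwise_p(dct[str(sample)], dct[control_sample])
                p_adj = min(1.0, p_raw * n_comp)
                fold = folds[str(sample)].fold
                results[float(t)] = (fold, p_adj)
                if p_adj < alpha and fold > 1.0:
                    any_significant = True
            per_condition[cond] = results
            cond_ok[cond] = any_significant and p_anova < alpha
        calls.append(
            ResponsivenessCall(
                gene=gene,
                per_condition=per_condition,
                anova_p=anova_p,
                responsive=all(cond_ok.values()),
            )
        )
    return calls


# ---------------------------------------------------------------------------
# Crystal-violet viability


def viability(
    od: "float | Mapping[str, float]",
    vehicle_od: float,
    mock_ratio: Optional[float] = None,
):
    """Crystal-violet viability: OD590(assay) / OD590(vehicle control),
    optionally expressed as fold over the mock (empty-vector) ratio.

    Accepts a single OD or a mapping of well -> OD (returns the same
    shape).  Non-positive ODs or a zero mock ratio are errors.
    """
    if vehicle_od <= 0:
        raise ValueError("vehicle OD must be positive")
    if mock_ratio is not None and mock_ratio <= 0:
        raise ValueError("mock ratio must be positive")

    def one(x: float) -> float:
        if x <= 0:
            raise ValueError("OD must be positive")
        ratio = x / vehicle_od
        return ratio / mock_ratio if mock_ratio is not None else ratio

    if isinstance(od, Mapping):
        return {well: one(float(x)) for well, x in od.items()}
    return one(float(od))
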