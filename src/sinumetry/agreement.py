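"""Method agreement (Bland-Altman) and reader reliability (three-level ICC).

Bland-Altman analysis summarises paired measurements from two methods by the
per-pair difference: its mean (systematic bias) and limits of agreement at
mean ± 2·SD.  Outlying pairs are flagged (|diff − mean| > 3·SD by default)
but never removed automatically.

Reader reliability uses a three-level random-effects decomposition of
repeated readings: patients, readers within patients, and residual replicate
error.  The inter-reader ICC is the patient variance share of the total,

    ICC = var_patient / (var_patient + var_reader + var_residual),

estimated by ANOVA method of moments on the (near-)balanced nested design
(negative moment estimates truncated at zero), with REML through statsmodels
as an alternative backend and a crossed readers-by-patients layout as an
alternative design.  The intra-reader ICC drops the reader level: each
reader's replicates are decomposed into between-patient and within-patient
variance and the components are pooled across readers.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .errors import DesignError, ValidationError


@dataclass(frozen=True)
class BlandAltmanResult:
    mean_diff: float
    sd_diff: float
    loa_low: float
    loa_high: float
    n: int
    n_outliers: int = 0


def bland_altman(a, b, *, loa_multiplier: float = 2.0,
                 outlier_sd: float = 3.0
                 ) -> tuple[BlandAltmanResult, pd.DataFrame]:
    """Agreement between two equally long vectors of paired measurements.

    Differences are ``a - b``; ``sd_diff`` is the sample (n−1) standard
    deviation; limits of agreement are mean ± ``loa_multiplier``·SD.  Pairs
    with |diff − mean| > ``outlier_sd``·SD are flagged in the returned table
    (column ``outlier``) for manual review, mirroring how gross outliers are
    handled in practice — reported, not dropped.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValidationError(
            f"paired vectors must be 1-D and equally long, got {a.shape} vs {b.shape}")
    if a.size < 2:
        raise ValidationError("need at least 2 pairs")
    diff = a - b
    mean = (a + b) / 2.0
    mean_diff = float(diff.mean())
    sd_diff = float(diff.std(ddof=1))
    outlier = (np.abs(diff - mean_diff) > outlier_sd * sd_diff) if sd_diff > 0 \
        else np.zeros_like(diff, dtype=bool)
    table = pd.DataFrame({"mean": mean, "diff": diff, "outlier": outlier})
    result = BlandAltmanResult(
        mean_diff=mean_diff, sd_diff=sd_diff,
        loa_low=mean_diff - loa_multiplier * sd_diff,
        loa_high=mean_diff + loa_multiplier * sd_diff,
        n=int(a.size), n_outliers=int(outlier.sum()))
    return result, table


def bland_altman_plot(table: pd.DataFrame, result: BlandAltmanResult, path,
                      *, xlabel: str = "mean of methods",
                      ylabel: str = "difference") -> None:
    """Scatter of differences against means with bias and LoA lines."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, (ax, hx) = plt.subplots(1, 2, figsize=(9, 4))
    ax.scatter(table["mean"], table["diff"], s=18, alpha=0.8)
    if table["outlier"].any():
        out = table[table["outlier"]]
        ax.scatter(out["mean"], out["diff"], s=40, facecolors="none",
                   edgecolors="red", label="flagged outlier")
        ax.legend(loc="best", fontsize=8)
    ax.axhline(result.mean_diff, color="k")
    for y in (result.loa_low, result.loa_high):
        ax.axhline(y, color="k", linestyle="--")
    ax.set_xlabel(xlabel)
    ax.set_ylabel(ylabel)
    hx.hist(table["diff"], bins=20, color="0.6")
    hx.axvline(result.mean_diff, color="k")
    hx.set_xlabel(ylabel)
    fig.tight_layout()
    fig.savefig(path, dpi=120)
    plt.close(fig)


@dataclass(frozen=True)
class IccResult:
    """Variance components and the derived intraclass correlation."""

    icc: float
    var_patient: float
    var_reader: float
    var_residual: float


READER_COLUMNS = ("patient_id", "reader_id", "replicate", "value")


def _check_reader_frame(data: pd.DataFrame) -> pd.DataFrame:
    missing = [c for c in READER_COLUMNS if c not in data.columns]
    if missing:
        raise ValidationError(f"reader data must have columns {READER_COLUMNS}, "
                              f"missing {missing}")
    if data["patient_id"].nunique() < 2:
        raise DesignError("need at least 2 patients to estimate a patient variance")
    return data


def _anova_nested(data: pd.DataFrame) -> tuple[float, float, float]:
    """Moment estimators for patient / reader-within-patient / residual
    variances on a balanced or near-balanced nested design.  Imbalance is
    handled with harmonic-mean cell sizes on cell/patient means (an
    unweighted-means approximation)."""
    cell = data.groupby(["patient_id", "reader_id"])["value"]
    cell_mean = cell.mean()
    cell_n = cell.size()
    grand = float(data["value"].mean())

    # residual: pooled within-cell variance
    df_e = int((cell_n - 1).sum())
    if df_e > 0:
        sse = float(((data["value"] - data.groupby(
            ["patient_id", "reader_id"])["value"].transform("mean")) ** 2).sum())
        var_e = sse / df_e
    else:
        var_e = 0.0  # single replicate per cell: residual confounded with reader

    n_tilde = float(1.0 / np.mean(1.0 / cell_n.to_numpy(dtype=float)))
    pat_of_cell = cell_mean.index.get_level_values(0)
    pat_mean = cell_mean.groupby(pat_of_cell).mean()
    readers_per_pat = cell_mean.groupby(pat_of_cell).size()
    b_tilde = float(1.0 / np.mean(1.0 / readers_per_pat.to_numpy(dtype=float)))

    # readers within patients, from cell means around patient means
    df_b = int((readers_per_pat - 1).sum())
    if df_b > 0:
        ssb = float(((cell_mean - pat_mean.reindex(pat_of_cell).to_numpy()) ** 2).sum())
        msb = ssb / df_b  # E[MSB] ~ var_e/ñ + var_r  (on cell means)
        var_r = max(0.0, msb - var_e / n_tilde)
    else:
        var_r = 0.0

    # patients, from patient means around the grand mean
    a = len(pat_mean)
    msa = float(((pat_mean - grand) ** 2).sum()) / (a - 1)
    # E[MSA on patient means] ~ var_p + var_r/b̃ + var_e/(b̃·ñ)
    var_p = max(0.0, msa - var_r / b_tilde - var_e / (b_tilde * n_tilde))
    return var_p, var_r, var_e


def _anova_crossed(data: pd.DataFrame) -> tuple[float, float, float]:
    """Moment estimators for the crossed two-way random model
    y = mu + patient + reader + residual (no interaction), balanced."""
    a = data["patient_id"].nunique()
    b = data["reader_id"].nunique()
    n = len(data) / (a * b)
    grand = float(data["value"].mean())
    pat_mean = data.groupby("patient_id")["value"].mean()
    rdr_mean = data.groupby("reader_id")["value"].mean()
    ssp = b * n * float(((pat_mean - grand) ** 2).sum())
    ssr = a * n * float(((rdr_mean - grand) ** 2).sum())
    sst = float(((data["value"] - grand) ** 2).sum())
    sse = sst - ssp - ssr
    df_e = len(data) - a - b + 1
    mse = sse / df_e if df_e > 0 else 0.0
    msp = ssp / (a - 1)
    msr = ssr / (b - 1) if b > 1 else 0.0
    var_e = max(0.0, mse)
    var_p = max(0.0, (msp - mse) / (b * n))
    var_r = max(0.0, (msr - mse) / (a * n))
    return var_p, var_r, var_e


def _reml_nested(data: pd.DataFrame) -> tuple[float, float, float]:
    import statsmodels.formula.api as smf

    df = data.rename(columns={"value": "y"}).copy()
    df["reader_id"] = df["reader_id"].astype(str)
    model = smf.mixedlm("y ~ 1", df, groups=df["patient_id"],
                        re_formula="1", vc_formula={"reader": "0 + C(reader_id)"})
    fit = model.fit(reml=True, method="lbfgs")
    var_p = max(0.0, float(np.asarray(fit.cov_re)[0, 0]))
    var_r = max(0.0, float(np.asarray(fit.vcomp)[0]))
    var_e = max(0.0, float(fit.scale))
    return var_p, var_r, var_e


def icc_inter_reader(data: pd.DataFrame, *, design: str = "nested",
                     method: str = "anova") -> IccResult:
    """Inter-reader ICC from a patients × readers (× replicates) table."""
    data = _check_reader_frame(data)
    if data["reader_id"].nunique() < 2:
        raise DesignError("inter-reader ICC needs at least 2 readers")
    if method == "anova":
        if design == "nested":
            var_p, var_r, var_e = _anova_nested(data)
        elif design == "crossed":
            var_p, var_r, var_e = _anova_crossed(data)
        else:
            raise ValidationError(f"unknown design {design!r}")
    elif method == "reml":
        var_p, var_r, var_e = _reml_nested(data)
    else:
        raise ValidationError(f"unknown method {method!r}")
    total = var_p + var_r + var_e
    icc = var_p / total if total > 0 else 0.0
    return IccResult(icc=float(icc), var_patient=var_p, var_reader=var_r,
                     var_residual=var_e)


def icc_intra_reader(data: pd.DataFrame) -> IccResult:
    """Intra-reader ICC: replicate agreement within each reader.

    For every reader with replicated readings, a one-way random decomposition
    across patients yields between-patient and within-patient (replicate)
    variances; components are averaged over readers.  The reader level is
    absorbed (a reader's own systematic offset does not hurt their own
    repeatability), so ``var_reader`` is reported as 0.
    """
    data = _check_reader_frame(data)
    comps = []
    for _, g in data.groupby("reader_id"):
        counts = g.groupby("patient_id")["replicate"].size()
        if (counts < 2).all():
            continue
        a = len(counts)
        if a < 2:
            continue
        n0 = float(1.0 / np.mean(1.0 / counts.to_numpy(dtype=float)))
        pat_mean = g.groupby("patient_id")["value"].mean()
        grand = float(g["value"].mean())
        msw_df = int((counts - 1).sum())
        ssw = float(((g["value"] - g.groupby("patient_id")["value"]
                      .transform("mean")) ** 2).sum())
        var_w = ssw / msw_df if msw_df > 0 else 0.0
        msb = float(((pat_mean - grand) ** 2).sum()) / (a - 1)
        var_b = max(0.0, msb - var_w / n0)
        comps.append((var_b, var_w))
    if not comps:
        raise DesignError("intra-reader ICC needs a reader with >= 2 replicates "
                          "on >= 2 patients")
    var_b = float(np.mean([c[0] for c in comps]))
    var_w = float(np.mean([c[1] for c in comps]))
    total = var_b + var_w
    icc = var_b / total if total > 0 else 0.0
    return IccResult(icc=float(icc), var_patient=var_b, var_reader=0.0,
                     var_residual=var_w)


def icc_three_level(data: pd.DataFrame, *, design: str = "nested",
                    method: str = "anova") -> tuple[IccResult, IccResult]:
    """Convenience wrapper returning (inter-reader, intra-reader) ICCs."""
    return (icc_inter_reader(data, design=design, method=method),
            icc_intra_reader(data))
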