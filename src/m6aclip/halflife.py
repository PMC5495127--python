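"""First-order mRNA decay fitting from actinomycin-D time courses.

After transcriptional shutoff the abundance of an mRNA follows
``A(t) = A0 * exp(-k t)``; the half-life is ``T1/2 = ln(2) / k``. The
model is fitted per transcript by log-linear least squares, pooling all
replicate points at each time, with a two-sided t test on the slope
(df = points - 2). Reliability filtering applies Benjamini-Hochberg
across transcripts and keeps FDR < 0.05 with k > 0.

Organised statsmodels-style: :class:`ExponentialDecayModel` is built
from a tidy time-course DataFrame; ``fit()`` returns a
:class:`DecayResults` carrying per-transcript estimates, standard
errors, p-values and a ``summary()`` table.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .stats import bh_adjust

LN2 = float(np.log(2.0))

TIMECOURSE_COLUMNS = ["transcript_id", "time_h", "replicate", "abundance"]


class ExponentialDecayModel:
    """Per-transcript first-order decay model for an ActD time course.

    Parameters
    ----------
    data:
        Tidy DataFrame with columns transcript_id, time_h, replicate,
        abundance. All replicate points at each time enter one pooled
        regression per transcript.
    size_factors:
        Optional mapping ``(time_h, replicate) -> factor`` (or DataFrame
        with those columns plus ``size_factor``) dividing abundances to
        remove library-depth differences between time points.
    pseudocount:
        Value substituted for zero abundances before the log transform
        (non-zero abundances are used as-is, so noise-free exponential
        input is recovered exactly).
    min_points:
        Minimum number of points with positive abundance for a fit.
    method:
        ``"ols"`` (log-linear least squares, default) or ``"nonlinear"``
        (Levenberg-Marquardt refinement of A0*exp(-kt), initialised
        from the OLS fit).
    replicate_handling:
        ``"pooled"`` (one regression over all replicate points,
        default) or ``"average"`` (fit each replicate separately and
        average the rate constants; the p-value is then a one-sample t
        test of the per-replicate slopes).
    drop_zero_tail:
        Drop trailing time points whose abundance is zero in every
        replicate (late-chase underflow) before fitting.
    """

    def __init__(self, data: pd.DataFrame, size_factors=None,
                 pseudocount: float = 0.5, min_points: int = 3,
                 method: str = "ols", replicate_handling: str = "pooled",
                 drop_zero_tail: bool = False):
        if method not in ("ols", "nonlinear"):
            raise ValueError(f"unknown method {method!r}")
        if replicate_handling not in ("pooled", "average"):
            raise ValueError(f"unknown replicate handling {replicate_handling!r}")
        self.method = method
        self.replicate_handling = replicate_handling
        self.drop_zero_tail = drop_zero_tail
        missing = set(TIMECOURSE_COLUMNS) - set(data.columns)
        if missing:
            raise ValueError(f"time course missing columns: {sorted(missing)}")
        if (data["abundance"] < 0).any():
            raise ValueError("abundances must be non-negative")
        self.data = data
        self.pseudocount = pseudocount
        self.min_points = min_points
        if isinstance(size_factors, pd.DataFrame):
            size_factors = {
                (r.time_h, r.replicate): r.size_factor
                for r in size_factors.itertuples()
            }
        self.size_factors = size_factors

    @classmethod
    def from_dataframe(cls, data: pd.DataFrame, **kwargs) -> "ExponentialDecayModel":
        return cls(data, **kwargs)

    @classmethod
    def from_tsv(cls, path, size_factors=None, **kwargs) -> "ExponentialDecayModel":
        return cls(pd.read_csv(path, sep="\t"), size_factors=size_factors, **kwargs)

    def _normalised(self) -> pd.DataFrame:
        df = self.data.copy()
        if self.size_factors is not None:
            factors = df.apply(
                lambda r: self.size_factors[(r["time_h"], r["replicate"])], axis=1
            )
            df["abundance"] = df["abundance"] / factors
        return df

    def _log_y(self, a: np.ndarray) -> np.ndarray:
        return np.log(np.where(a > 0, a, self.pseudocount))

    def _fit_one(self, t: np.ndarray, a: np.ndarray):
        """(k, se_k, p) for one set of (time, abundance) points."""
        res = sps.linregress(t, self._log_y(a))
        k, se, p = -res.slope, res.stderr, res.pvalue
        if self.method == "nonlinear" and k > 0:
            from scipy.optimize import curve_fit

            try:
                popt, pcov = curve_fit(
                    lambda x, a0, kk: a0 * np.exp(-kk * x), t, a,
                    p0=(float(np.exp(res.intercept)), k), maxfev=2000,
                )
                k, se = float(popt[1]), float(np.sqrt(pcov[1, 1]))
                p = float(2 * sps.t.sf(abs(k / se), df=len(t) - 2))
            except RuntimeError:
                pass  # keep the OLS estimate if refinement fails
        return k, se, p

    def fit(self) -> "DecayResults":
        rows = []
        for tid, grp in self._normalised().groupby("transcript_id", sort=True):
            if self.drop_zero_tail:
                times = sorted(grp["time_h"].unique(), reverse=True)
                for tp in times[:-1]:
                    if (grp.loc[grp["time_h"] == tp, "abundance"] > 0).any():
                        break
                    grp = grp[grp["time_h"] != tp]
            t = grp["time_h"].to_numpy(dtype=float)
            a = grp["abundance"].to_numpy(dtype=float)
            usable = int((a > 0).sum())
            if usable < self.min_points or np.unique(t).size < 2:
                rows.append(
                    dict(transcript_id=tid, k=np.nan, se_k=np.nan,
                         p_value=np.nan, halflife_h=np.nan,
                         n_points=len(a), flag="insufficient")
                )
                continue
            if self.replicate_handling == "average":
                ks = []
                for _, rep_grp in grp.groupby("replicate"):
                    rt = rep_grp["time_h"].to_numpy(dtype=float)
                    ra = rep_grp["abundance"].to_numpy(dtype=float)
                    if np.unique(rt).size < 2:
                        continue
                    ks.append(-sps.linregress(rt, self._log_y(ra)).slope)
                k = float(np.mean(ks))
                se = float(sps.sem(ks)) if len(ks) > 1 else np.nan
                if len(ks) > 1 and np.ptp(ks) > 0:
                    p = float(sps.ttest_1samp(ks, 0.0).pvalue)
                elif len(ks) > 1:
                    p = 1e-300 if k != 0 else 1.0  # identical replicate slopes
                else:
                    p = np.nan
            else:
                k, se, p = self._fit_one(t, a)
            flag = "ok" if k > 0 else "non_decaying"
            if np.isfinite(p):
                p = float(np.clip(p, 1e-300, 1.0))  # exact fits give p = 0
            rows.append(
                dict(
                    transcript_id=tid, k=k, se_k=se, p_value=p,
                    halflife_h=LN2 / k if k > 0 else np.nan,
                    n_points=len(a), flag=flag,
                )
            )
        frame = pd.DataFrame(rows)
        fitted = frame["flag"].isin(("ok", "non_decaying")) & np.isfinite(
            frame["p_value"].astype(float)
        )
        frame["fdr"] = np.nan
        if fitted.any():
            frame.loc[fitted, "fdr"] = bh_adjust(
                frame.loc[fitted, "p_value"].to_numpy()
            )
        return DecayResults(model=self, frame=frame)


@dataclass
class DecayResults:
    """Per-transcript decay fits with multiple-testing-adjusted reliability."""

    model: ExponentialDecayModel
    frame: pd.DataFrame

    def filter_reliable(self, fdr_max: float = 0.05) -> pd.DataFrame:
        """Fits with BH FDR < ``fdr_max`` and a positive decay rate."""
        f = self.frame
        return f[(f["fdr"] < fdr_max) & (f["k"] > 0)].reset_index(drop=True)

    def halflife(self, transcript_id: str) -> float:
        row = self.frame[self.frame["transcript_id"] == transcript_id]
        if row.empty:
            raise KeyError(transcript_id)
        return float(row["halflife_h"].iloc[0])

    def summary(self, fdr_max: float = 0.05) -> str:
        f = self.frame
        reliable = self.filter_reliable(fdr_max)
        lines = [
            "Exponential decay fits (A(t) = A0 exp(-k t), T1/2 = ln2/k)",
            f"  transcripts fitted     : {int(f['flag'].isin(('ok', 'non_decaying')).sum())}",
            f"  non-decaying (k <= 0)  : {int((f['flag'] == 'non_decaying').sum())}",
            f"  reliable (FDR<{fdr_max:g}, k>0): {len(reliable)}",
        ]
        if len(reliable):
            q = reliable["halflife_h"].quantile([0.25, 0.5, 0.75])
            lines.append(
                f"  T1/2 quartiles (h)     : "
                f"{q.iloc[0]:.2f} / {q.iloc[1]:.2f} / {q.iloc[2]:.2f}"
            )
        return "\n".join(lines)

    def to_tsv(self, path) -> None:
        self.frame.to_csv(path, sep="\t", index=False)


def fit_decay(timecourse: pd.DataFrame, size_factors=None, **kwargs) -> DecayResults:
    """Convenience wrapper: build the model and fit in one call."""
    return ExponentialDecayModel(timecourse, size_factors=size_factors, **kwargs).fit()


def filter_reliable(results: DecayResults, fdr_max: float = 0.05) -> pd.DataFrame:
    return results.filter_reliable(fdr_max)


# ---- m6A content vs half-life --------------------------------------------

def m6a_content_groups(peaks_per_transcript: pd.DataFrame) -> pd.DataFrame:
    """Label transcripts none/single/multiple by m6A peak count.

    Input: one row per transcript with ``transcript_id``, ``n_peaks``
    and optional ``region`` (none/CDS/3UTR/both).
    """
    df = peaks_per_transcript.copy()
    df["group"] = pd.cut(
        df["n_peaks"], bins=[-1, 0, 1, np.inf], labels=["none", "single", "multiple"]
    ).astype(str)
    return df


def content_vs_halflife(groups: pd.DataFrame, fits: pd.DataFrame,
                        group_col: str = "group"
                        ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Stratified T1/2 summaries plus two-sided rank-sum tests.

    ``groups`` carries transcript_id and a stratum column; ``fits`` is a
    reliable-fit table with halflife_h. Returns (summary per stratum,
    pairwise Wilcoxon rank-sum p-values). Strata with < 2 members get a
    summary but no test.
    """
    merged = groups.merge(fits, on="transcript_id")
    summaries = (
        merged.groupby(group_col)["halflife_h"]
        .agg(n="size", median="median",
             q1=lambda s: s.quantile(0.25), q3=lambda s: s.quantile(0.75))
        .reset_index()
    )
    tests = []
    strata = sorted(merged[group_col].unique())
    for i, ga in enumerate(strata):
        for gb in strata[i + 1:]:
            xa = merged.loc[merged[group_col] == ga, "halflife_h"]
            xb = merged.loc[merged[group_col] == gb, "halflife_h"]
            if len(xa) < 2 or len(xb) < 2:
                continue
            p = sps.mannwhitneyu(xa, xb, alternative="two-sided").pvalue
            tests.append({"group_a": ga, "group_b": gb, "p_value": float(p),
                          "n_a": len(xa), "n_b": len(xb)})
    return summaries, pd.DataFrame(tests)


def halflife_change(fits_wt: pd.DataFrame, fits_ko: pd.DataFrame,
                    lost_per_transcript: pd.DataFrame | None = None
                    ) -> pd.DataFrame:
    """Per-transcript T1/2(KO) / T1/2(WT) ratios for transcripts
    reliable in both conditions, annotated with lost-peak counts/regions."""
    wt = fits_wt[["transcript_id", "halflife_h"]].rename(
        columns={"halflife_h": "halflife_wt"}
    )
    ko = fits_ko[["transcript_id", "halflife_h"]].rename(
        columns={"halflife_h": "halflife_ko"}
    )
    df = wt.merge(ko, on="transcript_id")
    df = df[(df["halflife_wt"] > 0) & (df["halflife_ko"] > 0)].copy()
    df["ratio"] = df["halflife_ko"] / df["halflife_wt"]
    if lost_per_transcript is not None:
        df = df.merge(
            lost_per_transcript[
                [c for c in ("transcript_id", "n_lost", "lost_region")
                 if c in lost_per_transcript.columns]
            ],
            on="transcript_id", how="left",
        )
        df["n_lost"] = df["n_lost"].fillna(0).astype(int)
        if "lost_region" in df.columns:
            df["lost_region"] = df["lost_region"].fillna("none")
    return df


def compare_ratio_strata(change: pd.DataFrame, stratum_col: str = "n_lost_group"
                         ) -> pd.DataFrame:
    """Distribution tests on T1/2 ratios across loss strata.

    Per stratum: median ratio, one-sample Wilcoxon p for log-ratio != 0,
    and a KS p against the zero-loss stratum when present.
    """
    ref = change[change.get("n_lost", 0) == 0]["ratio"] if "n_lost" in change else None
    rows = []
    for name, grp in change.groupby(stratum_col):
        logr = np.log(grp["ratio"].to_numpy())
        row = {"stratum": name, "n": len(grp),
               "median_ratio": float(grp["ratio"].median())}
        if len(grp) >= 2 and np.ptp(logr) > 0:
            row["wilcoxon_p"] = float(sps.wilcoxon(logr).pvalue)
        else:
            row["wilcoxon_p"] = np.nan
        if ref is not None and len(ref) >= 2 and len(grp) >= 2:
            row["ks_p_vs_no_loss"] = float(sps.ks_2samp(grp["ratio"], ref).pvalue)
        rows.append(row)
    return pd.DataFrame(rows)


# ---- inter-peak spacing --------------------------------------------------

def inter_peak_spacing(peak_positions: dict[str, list[int]]) -> pd.DataFrame:
    """Median adjacent-peak spacing per transcript (transcript space).

    Transcripts with fewer than two peaks are excluded.
    """
    rows = []
    for tid, positions in sorted(peak_positions.items()):
        if len(positions) < 2:
            continue
        pos = np.sort(np.asarray(positions))
        spacings = np.diff(pos)
        rows.append(
            {"transcript_id": tid, "n_peaks": len(pos),
             "median_spacing": float(np.median(spacings))}
        )
    return pd.DataFrame(rows)


def spacing_vs_halflife(spacing: pd.DataFrame, fits: pd.DataFrame,
                        match_peak_counts: bool = False) -> dict:
    """Compare adjacent-peak spacing between the fastest- and
    slowest-turnover half-life quartiles (rank-sum test).

    With ``match_peak_counts`` the comparison is restricted to peak
    counts present in both quartiles, mirroring a count-matched control.
    """
    from .metagene import quartile_assign

    merged = spacing.merge(fits[["transcript_id", "halflife_h"]], on="transcript_id")
    if len(merged) < 8:
        raise ValueError("too few transcripts with >= 2 peaks for quartiles")
    merged["quartile"] = quartile_assign(merged["halflife_h"].to_numpy())
    fast = merged[merged["quartile"] == "Q1"]
    slow = merged[merged["quartile"] == "Q4"]
    if match_peak_counts:
        common = set(fast["n_peaks"]) & set(slow["n_peaks"])
        fast = fast[fast["n_peaks"].isin(common)]
        slow = slow[slow["n_peaks"].isin(common)]
    p = sps.mannwhitneyu(
        fast["median_spacing"], slow["median_spacing"], alternative="two-sided"
    ).pvalue
    return {
        "fast_median_spacing": float(fast["median_spacing"].median()),
        "slow_median_spacing": float(slow["median_spacing"].median()),
        "p_value": float(p),
        "n_fast": len(fast),
        "n_slow": len(slow),
    }
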