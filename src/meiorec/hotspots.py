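"""Hotspot symmetry metrics and symmetry-stratified event tests.

PRDM9 in a B6 x CAST hybrid can bind the two homologues unequally; the
B6 binding/cutting ratio x (fraction of allele-assignable ChIP reads
from the B6 chromosome) summarises this per hotspot, and symmetry
4x(1-x) ranges from 0 (fully one-sided) to 1 (equal binding).  DSBs at
asymmetric hotspots face a poorly-bound homologue and repair slowly;
this module quantifies the resulting depletion of CO/NCO events against
DMC1-predicted expectations, runs the symmetry-vs-SNP-density binomial
GLM, and measures event positioning around PRDM9 motifs.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from statsmodels.stats.proportion import proportion_confint


# ---------------------------------------------------------------------------
# Per-hotspot metrics


def b6_ratio(b6_count, cast_count, min_informative: int = 10):
    """B6 read fraction x = b6/(b6+cast), or NaN below the informative-read
    threshold (no silent zeros)."""
    b6 = np.asarray(b6_count, dtype=float)
    cast = np.asarray(cast_count, dtype=float)
    if np.any(b6 < 0) or np.any(cast < 0):
        raise ValueError("counts must be non-negative")
    tot = b6 + cast
    with np.errstate(invalid="ignore", divide="ignore"):
        x = np.where(tot >= min_informative, b6 / tot, np.nan)
    return float(x) if x.ndim == 0 else x


def b6_ratio_background_corrected(
    b6_count, cast_count, input_b6, input_cast,
    factor: float = 1.0, min_informative: int = 10,
):
    """H3K4me3 variant: subtract a scaled input-chromatin estimate from
    each homologue's count before forming the ratio."""
    b6 = np.maximum(np.asarray(b6_count, float) - factor * np.asarray(input_b6, float), 0)
    cast = np.maximum(
        np.asarray(cast_count, float) - factor * np.asarray(input_cast, float), 0
    )
    return b6_ratio(b6, cast, min_informative)


def symmetry(x):
    """Hotspot symmetry 4x(1-x); 1 at equal binding, 0 at fully one-sided."""
    x = np.asarray(x, dtype=float)
    if np.any((x < 0) | (x > 1)):
        raise ValueError("x must be in [0, 1]")
    s = 4.0 * x * (1.0 - x)
    return float(s) if s.ndim == 0 else s


def homologous_heat(x, h, recipient: str):
    """Heat attributed to the repair-template (non-recipient) homologue.

    A DSB on the CAST chromosome repairs off the B6 homologue, whose
    binding fraction is x, so homologous heat is x*h; recipient B6 gives
    (1-x)*h.
    """
    if recipient not in ("B6", "CAST"):
        raise ValueError("recipient must be 'B6' or 'CAST'")
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("heat must be positive")
    out = np.where(np.isnan(x), np.nan, (x if recipient == "CAST" else 1.0 - x) * h)
    return float(out) if out.ndim == 0 else out


def average_homologous_heat(x, h):
    """2hx(1-x): homologous heat averaged over the initiating homologue
    (weights x and 1-x)."""
    x = np.asarray(x, dtype=float)
    h = np.asarray(h, dtype=float)
    if np.any(h <= 0):
        raise ValueError("heat must be positive")
    out = 2.0 * h * x * (1.0 - x)
    return float(out) if out.ndim == 0 else out


# ---------------------------------------------------------------------------
# Symmetry binning and observed-vs-expected


_BIN_LABELS3 = ("asymmetric", "intermediate", "symmetric")


def bin_by_symmetry(
    hotspots: pd.DataFrame,
    enrichment_col: str = "dmc1_total",
    symmetry_col: str = "symmetry",
    n_bins: int = 3,
) -> pd.DataFrame:
    """Cut hotspots into symmetry bins of equal predicted event mass.

    Hotspots are sorted by symmetry and the cumulative enrichment
    (predicted events) is cut into ``n_bins`` equal-mass groups, so each
    bin predicts the same number of events.  Ties in symmetry stay in
    one bin.  Returns the input with a ``sym_bin`` column.
    """
    df = hotspots.dropna(subset=[symmetry_col, enrichment_col]).copy()
    if df[symmetry_col].nunique() <= 1:
        raise ValueError("degenerate binning: all symmetry values equal")
    df = df.sort_values(symmetry_col, kind="mergesort")
    mass = df[enrichment_col].to_numpy(dtype=float)
    cum = np.cumsum(mass)
    total = cum[-1]
    if total <= 0:
        raise ValueError("total enrichment must be positive")
    frac_upper = cum / total
    raw_bin = np.minimum((frac_upper * n_bins - 1e-12).astype(int), n_bins - 1)
    # keep equal symmetry values together (ties in one bin)
    sym = df[symmetry_col].to_numpy()
    for i in range(1, len(raw_bin)):
        if sym[i] == sym[i - 1]:
            raw_bin[i] = raw_bin[i - 1]
    labels = (
        list(_BIN_LABELS3) if n_bins == 3 else [f"bin_{i}" for i in range(n_bins)]
    )
    df["sym_bin"] = [labels[b] for b in raw_bin]
    df["sym_bin"] = pd.Categorical(df["sym_bin"], categories=labels, ordered=True)
    return df


@dataclass
class SymmetryBinResult:
    bin_labels: list
    expected_fraction: np.ndarray
    observed: dict  # class -> counts per bin
    observed_fraction: dict
    ci_low: dict
    ci_high: dict
    chi2: dict
    pvalue: dict
    dropped: dict  # class -> events not mapped to a binned hotspot


def observed_vs_expected(
    events_df: pd.DataFrame,
    binned_hotspots: pd.DataFrame,
    detection_weights: pd.Series | dict | None = None,
    class_col: str = "kind",
    enrichment_col: str = "dmc1_total",
) -> SymmetryBinResult:
    """Chi-square test of event counts per symmetry bin against the
    enrichment-predicted (optionally power-weighted) expectation.

    ``events_df`` needs hotspot_id and a class column; events whose
    hotspot is not in the binned table are dropped (counted).
    """
    labels = list(binned_hotspots["sym_bin"].cat.categories)
    if len(labels) < 2:
        raise ValueError("need >= 2 bins for a chi-square test")
    hs = binned_hotspots.set_index("hotspot_id")
    w = hs[enrichment_col].astype(float)
    if detection_weights is not None:
        dw = pd.Series(detection_weights)
        w = w * dw.reindex(hs.index).fillna(0.0)
    mass = w.groupby(hs["sym_bin"], observed=False).sum().reindex(labels).fillna(0.0)
    if (mass <= 0).any():
        raise ValueError("zero expected mass in a symmetry bin")
    expected_frac = (mass / mass.sum()).to_numpy()

    observed, obs_frac, ci_lo, ci_hi, chi2s, ps, dropped = (
        {}, {}, {}, {}, {}, {}, {},
    )
    for cls, sub in events_df.groupby(class_col):
        mapped = sub[sub["hotspot_id"].isin(hs.index)]
        dropped[cls] = len(sub) - len(mapped)
        bins = hs.loc[mapped["hotspot_id"], "sym_bin"]
        counts = (
            bins.value_counts().reindex(labels).fillna(0).to_numpy(dtype=float)
        )
        n = counts.sum()
        if n == 0:
            continue
        chi2, p = stats.chisquare(counts, f_exp=expected_frac * n)
        observed[cls] = counts
        obs_frac[cls] = counts / n
        lo, hi = proportion_confint(counts.astype(int), int(n), method="wilson")
        ci_lo[cls], ci_hi[cls] = np.asarray(lo), np.asarray(hi)
        chi2s[cls], ps[cls] = float(chi2), float(p)
    return SymmetryBinResult(
        bin_labels=labels,
        expected_fraction=expected_frac,
        observed=observed,
        observed_fraction=obs_frac,
        ci_low=ci_lo,
        ci_high=ci_hi,
        chi2=chi2s,
        pvalue=ps,
        dropped=dropped,
    )


def initiation_fraction_less_bound(
    events_df: pd.DataFrame,
    hotspots: pd.DataFrame,
    bin_col: str = "sym_bin",
    B: int = 500,
    rng: np.random.Generator | None = None,
) -> pd.DataFrame:
    """Initiation on the less-H3K4me3-bound homologue, observed vs predicted.

    Per symmetry class: the mean H3K4me3 fraction on the less-bound
    homologue, the mean DMC1 fraction on that homologue, and the
    fraction of events (per class) whose recipient is that homologue,
    with bootstrap CIs on the observed fractions.

    ``events_df`` needs hotspot_id, recipient and a class column 'kind';
    ``hotspots`` needs x_h3k4, x_dmc1 and the bin column.
    """
    if rng is None:
        rng = np.random.default_rng()
    hs = hotspots.dropna(subset=["x_h3k4", "x_dmc1"]).set_index("hotspot_id")
    if len(hs) == 0:
        raise ValueError("no informative hotspots")
    ev = events_df[
        events_df["hotspot_id"].isin(hs.index)
        & events_df["recipient"].isin(["B6", "CAST"])
    ]
    if len(ev) == 0:
        raise ValueError("no assigned events")
    lb_is_b6 = hs["x_h3k4"] < 0.5  # less-bound homologue per hotspot
    h3_lb = np.minimum(hs["x_h3k4"], 1 - hs["x_h3k4"])
    d_lb = np.where(lb_is_b6, hs["x_dmc1"], 1 - hs["x_dmc1"])
    rows = []
    for label, hsub in hs.groupby(bin_col, observed=True):
        esub = ev[ev["hotspot_id"].isin(hsub.index)]
        on_lb = (
            esub["recipient"].to_numpy()
            == np.where(lb_is_b6.loc[esub["hotspot_id"]], "B6", "CAST")
        )
        for cls, csub in pd.Series(on_lb).groupby(esub["kind"].to_numpy()):
            arr = csub.to_numpy(dtype=float)
            if len(arr) == 0:
                continue
            boots = [
                arr[rng.integers(0, len(arr), len(arr))].mean() for _ in range(B)
            ]
            rows.append(
                {
                    "sym_bin": label,
                    "class": cls,
                    "h3k4_lessbound_frac": float(h3_lb.loc[hsub.index].mean()),
                    "dmc1_lessbound_frac": float(
                        np.asarray(d_lb)[hs.index.get_indexer(hsub.index)].mean()
                    ),
                    "observed_frac": float(arr.mean()),
                    "ci_low": float(np.percentile(boots, 2.5)),
                    "ci_high": float(np.percentile(boots, 97.5)),
                    "n_events": int(len(arr)),
                }
            )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# Motif disruption and positioning


def motif_disruption_fraction(
    hotspots: pd.DataFrame,
    snp_map,
    posterior_min: float = 0.99,
    min_informative: int = 20,
    min_reads_per_homologue: int = 5,
    bins=(0.0, 0.05, 0.2, 0.8, 0.95, 1.0),
) -> pd.DataFrame:
    """Fraction of hotspots with a variant inside the PRDM9 motif, per
    B6-initiation bin.

    Hotspots pass when the motif is confidently placed (posterior >
    ``posterior_min``), DMC1 informative reads reach ``min_informative``
    and (when per-homologue coverage columns ``cov_b6``/``cov_cast``
    exist) each homologue has ``min_reads_per_homologue`` reads.
    """
    hs = hotspots.copy()
    inf = hs["dmc1_b6"] + hs["dmc1_cast"]
    keep = (hs["motif_posterior"] > posterior_min) & (inf >= min_informative)
    if {"cov_b6", "cov_cast"} <= set(hs.columns):
        keep &= (hs["cov_b6"] >= min_reads_per_homologue) & (
            hs["cov_cast"] >= min_reads_per_homologue
        )
    hs = hs[keep].copy()
    hs["x_init"] = hs["dmc1_b6"] / inf[keep]
    has_var = []
    for _, row in hs.iterrows():
        cpos = snp_map.pos[row["chrom"]]
        lo = np.searchsorted(cpos, row["motif_start"], side="left")
        hi = np.searchsorted(cpos, row["motif_end"], side="right")
        has_var.append(hi > lo)
    hs["motif_has_variant"] = has_var
    hs["init_bin"] = pd.cut(hs["x_init"], bins=list(bins), include_lowest=True)
    out = (
        hs.groupby("init_bin", observed=False)["motif_has_variant"]
        .agg(["mean", "size"])
        .reset_index()
        .rename(columns={"mean": "fraction_disrupted", "size": "n_hotspots"})
    )
    return out


def snp_density_around(hotspots: pd.DataFrame, snp_map, half_widths=(100, 500, 800)):
    """Per-hotspot SNP densities (per bp) around the motif center."""
    out = {}
    for w in half_widths:
        dens = np.empty(len(hotspots))
        for i, (_, row) in enumerate(hotspots.iterrows()):
            cpos = snp_map.pos[row["chrom"]]
            lo = np.searchsorted(cpos, row["motif_center"] - w, "left")
            hi = np.searchsorted(cpos, row["motif_center"] + w, "right")
            dens[i] = (hi - lo) / (2.0 * w)
        out[f"snp_density_{w}"] = dens
    return pd.DataFrame(out, index=hotspots.index)


def glm_symmetry_vs_density(
    hotspots: pd.DataFrame,
    snp_map,
    response_col: str = "has_event",
    detection_weights: pd.Series | None = None,
    rng: np.random.Generator | None = None,
):
    """Binomial GLM: does symmetry or local SNP density predict events?

    Predictors: DMC1 symmetry, log(H3K4me3 enrichment + 1e-4), and SNP
    densities at +/-100, 500, 800 bp around the motif.  For NCOs the
    hotspot set is first resampled with replacement proportional to the
    supplied detection weights (power correction), so some hotspots
    appear several times.  Returns (coefficient table, statsmodels
    results, separation_flag).
    """
    hs = hotspots.copy()
    if detection_weights is not None:
        if rng is None:
            rng = np.random.default_rng()
        w = pd.Series(detection_weights).reindex(hs["hotspot_id"]).fillna(0.0).to_numpy()
        if w.sum() <= 0:
            raise ValueError("zero total detection weight")
        idx = rng.choice(len(hs), size=len(hs), replace=True, p=w / w.sum())
        hs = hs.iloc[idx].reset_index(drop=True)
    y = hs[response_col].astype(float).to_numpy()
    if y.min() == y.max():
        raise ValueError("constant response; degenerate fit")
    X = pd.DataFrame(
        {
            "symmetry_dmc1": hs["symmetry"].to_numpy(dtype=float),
            "log_h3k4": np.log(hs["h3k4_total"].to_numpy(dtype=float) + 1e-4),
        },
        index=hs.index,
    )
    X = pd.concat([X, snp_density_around(hs, snp_map)], axis=1)
    X = sm.add_constant(X)
    separated = False
    with warnings.catch_warnings(record=True) as caught:
        warnings.simplefilter("always")
        model = sm.GLM(y, X, family=sm.families.Binomial())
        try:
            res = model.fit()
        except Exception as exc:  # perfect separation raises in some versions
            warnings.warn(f"separation or convergence failure: {exc}")
            res = model.fit_regularized(alpha=1e-4, L1_wt=0.0)
            separated = True
        for wmsg in caught:
            if "eparation" in str(wmsg.message) or "onverge" in str(wmsg.message):
                separated = True
    params = np.asarray(res.params)
    if hasattr(res, "bse"):
        bse = np.asarray(res.bse)
        pvals = np.asarray(res.pvalues)
    else:  # regularized fallback has no covariance
        bse = np.full_like(params, np.nan)
        pvals = np.full_like(params, np.nan)
    table = pd.DataFrame(
        {"coef": params, "stderr": bse, "pvalue": pvals}, index=X.columns
    )
    return table, res, separated


def event_motif_distance(
    events, hotspots: pd.DataFrame, snp_map, max_dist: int = 1000,
    bin_width: int = 50,
):
    """Distances from events to their motif, SNP-density normalized.

    Two variants per event: the distance from the motif center to the
    nearest converted marker (0 if a marker falls inside the motif) and
    the distance to the midpoint of the minimal tract.  Events farther
    than ``max_dist`` from every motif are unassigned.  The histogram of
    the first variant is divided by the SNP count per distance bin
    (pooled over motifs) to correct for detection power.
    """
    if len(hotspots) == 0:
        raise ValueError("no motifs")
    hs_by_chrom = {c: sub for c, sub in hotspots.groupby("chrom")}
    d_nearest, d_mid = [], []
    for ev in events:
        sub = hs_by_chrom.get(ev.chrom)
        if sub is None:
            continue
        centers = sub["motif_center"].to_numpy()
        mid = ev.midpoint
        j = int(np.argmin(np.abs(centers - mid)))
        if abs(centers[j] - mid) > max_dist:
            continue
        row = sub.iloc[j]
        pos = np.asarray(ev.positions)
        inside = (pos >= row["motif_start"]) & (pos <= row["motif_end"])
        d_nearest.append(
            0.0 if inside.any() else float(np.min(np.abs(pos - row["motif_center"])))
        )
        d_mid.append(abs(mid - row["motif_center"]))
    edges = np.arange(0, max_dist + bin_width, bin_width)
    hist, _ = np.histogram(d_nearest, bins=edges)
    snp_hist = np.zeros(len(edges) - 1)
    for chrom, sub in hs_by_chrom.items():
        cpos = snp_map.pos[chrom]
        for c in sub["motif_center"].to_numpy():
            lo = np.searchsorted(cpos, c - max_dist, "left")
            hi = np.searchsorted(cpos, c + max_dist, "right")
            if hi > lo:
                h, _ = np.histogram(np.abs(cpos[lo:hi] - c), bins=edges)
                snp_hist += h
    with np.errstate(invalid="ignore", divide="ignore"):
        normalized = np.where(snp_hist > 0, hist / snp_hist, np.nan)
    return {
        "distance_nearest_marker": np.asarray(d_nearest),
        "distance_tract_midpoint": np.asarray(d_mid),
        "bin_edges": edges,
        "histogram": hist,
        "snp_counts": snp_hist,
        "normalized": normalized,
    }
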