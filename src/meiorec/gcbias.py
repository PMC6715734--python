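"""GC-biased gene conversion and the two-pathway repair model.

Gene conversions at Weak/Strong (A,T vs G,C) SNPs can transmit G/C
alleles preferentially.  The module classifies converted sites by
recipient/donor base class, measures the W->S fraction in subsets
(single- vs multi-SNP tracts, nearest-SNP distance strata, sexes,
controlling alleles), and implements a two-pathway model: the
donor-biased pathway converts every observed heteroduplex, while a
GC-restoring pathway acts with probability p at Strong-recipient
single-mismatch heteroduplexes and erases the event.  With DSBs equally
likely on either homologue the observed W->S fraction among surviving
conversions is 1/(2-p): p = 0.53 reproduces the 68% bias, and a
mechanism restricted to one of the two Strong bases caps the bias at
1/(2-0.5) = 67%.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

_STRONG = frozenset("GC")
_COMPLEMENT = {"A": "T", "T": "A", "G": "C", "C": "G"}


def base_class(base: str) -> str:
    return "S" if base in _STRONG else "W"


def strand_equivalent_label(recipient: str, donor: str) -> str:
    """Canonical label pooling a base pair with its reverse complement
    (e.g. C->A and G->T are one Strong-to-Weak transversion type)."""
    a = (recipient, donor)
    b = (_COMPLEMENT[recipient], _COMPLEMENT[donor])
    r, d = min(a, b)
    return f"{r}>{d}"


# ---------------------------------------------------------------------------
# Conversion records


@dataclass
class ConversionRecord:
    event_id: int
    recipient_base: Optional[str]
    donor_base: Optional[str]
    recipient_class: str  # S | W
    donor_class: str
    pair_label: Optional[str]  # strand-equivalent label
    tract_size_class: str  # single | multi
    nearest_snp_bp: float
    controlling_allele: str = "Unknown"
    sex: str = "unknown"


def classify_conversions(ncos, snp_map, hotspots: pd.DataFrame | None = None,
                         sex_of: dict | None = None) -> list:
    """Label every converted site of every NCO by donor/recipient base.

    The recipient base is the allele that was replaced (the allele of
    the cut homologue), the donor the allele gained.  When the recipient
    homologue is unknown the S/W classes are still well defined for
    W<->S SNPs (one allele strong, one weak: the donor is the observed
    gained allele), so such records keep their classes; S<->S and W<->W
    sites with unknown recipient are dropped (counted via the returned
    list length vs input sites).
    """
    ctrl_by_id = {}
    if hotspots is not None:
        ctrl_by_id = dict(
            zip(hotspots["hotspot_id"], hotspots["controlling_allele"])
        )
    records = []
    for ei, ev in enumerate(ncos):
        cpos = snp_map.pos[ev.chrom]
        b6 = snp_map.allele_b6[ev.chrom]
        cast = snp_map.allele_cast[ev.chrom]
        size_class = "single" if ev.n_converted == 1 else "multi"
        ctrl = ctrl_by_id.get(ev.hotspot_id, "Unknown")
        sex = (sex_of or {}).get(getattr(ev, "parent", None), "unknown")
        for i, snp_i in enumerate(ev.snp_indices):
            donor_is_cast = bool(ev.donor_is_cast[i])
            donor = cast[snp_i] if donor_is_cast else b6[snp_i]
            recipient = b6[snp_i] if donor_is_cast else cast[snp_i]
            # distance to the nearest other SNP
            cands = []
            if snp_i > 0:
                cands.append(cpos[snp_i] - cpos[snp_i - 1])
            if snp_i + 1 < len(cpos):
                cands.append(cpos[snp_i + 1] - cpos[snp_i])
            nearest = float(min(cands)) if cands else float("inf")
            records.append(
                ConversionRecord(
                    event_id=ei,
                    recipient_base=str(recipient),
                    donor_base=str(donor),
                    recipient_class=base_class(str(recipient)),
                    donor_class=base_class(str(donor)),
                    pair_label=strand_equivalent_label(str(recipient), str(donor)),
                    tract_size_class=size_class,
                    nearest_snp_bp=nearest,
                    controlling_allele=str(ctrl),
                    sex=sex,
                )
            )
    return records


def records_to_frame(records) -> pd.DataFrame:
    return pd.DataFrame([r.__dict__ for r in records])


# ---------------------------------------------------------------------------
# Bias fractions and tests


def gc_bias_fraction(records, confidence: float = 0.95):
    """Fraction of W->S conversions among W<->S records.

    Returns (fraction, (ci_low, ci_high), p) with an exact (Clopper-
    Pearson) binomial CI and a two-sided exact test against 0.5.
    """
    ws = [
        r for r in records
        if {r.recipient_class, r.donor_class} == {"S", "W"}
    ]
    if not ws:
        raise ValueError("no W<->S conversion records")
    k = sum(1 for r in ws if r.recipient_class == "W")
    n = len(ws)
    test = stats.binomtest(k, n, 0.5)
    ci = test.proportion_ci(confidence_level=confidence, method="exact")
    return k / n, (float(ci.low), float(ci.high)), float(test.pvalue)


def single_vs_multi_test(records) -> float:
    """Fisher exact two-sided p for W->S vs S->W in single- vs multi-SNP
    tracts (2x2 table, minimum-likelihood two-sided convention)."""
    table = np.zeros((2, 2), dtype=int)
    for r in records:
        if {r.recipient_class, r.donor_class} != {"S", "W"}:
            continue
        i = 0 if r.tract_size_class == "single" else 1
        j = 0 if r.recipient_class == "W" else 1
        table[i, j] += 1
    if table.sum(axis=1).min() == 0:
        raise ValueError("both tract-size classes must be nonempty")
    _, p = stats.fisher_exact(table, alternative="two-sided")
    return float(p)


def distance_stratified_bias(records, bins=None) -> pd.DataFrame:
    """Per-bin W->S fraction with exact binomial CIs, stratifying W<->S
    records by distance to the nearest neighbouring SNP (log-spaced bins
    by default).  Sites nearer than typical tract lengths share tracts
    with their neighbour and lose the bias; isolated sites (>100 bp)
    show the full single-site bias."""
    ws = [
        r for r in records
        if {r.recipient_class, r.donor_class} == {"S", "W"}
        and np.isfinite(r.nearest_snp_bp)
    ]
    if bins is None:
        bins = np.concatenate([np.geomspace(1, 1000, 7), [np.inf]])
    d = np.array([r.nearest_snp_bp for r in ws])
    w2s = np.array([r.recipient_class == "W" for r in ws])
    idx = np.digitize(d, bins) - 1
    rows = []
    for b in range(len(bins) - 1):
        m = idx == b
        n = int(m.sum())
        if n == 0:
            rows.append((bins[b], bins[b + 1], 0, np.nan, np.nan, np.nan))
            continue
        k = int(w2s[m].sum())
        ci = stats.binomtest(k, n, 0.5).proportion_ci(method="exact")
        rows.append((bins[b], bins[b + 1], n, k / n, ci.low, ci.high))
    return pd.DataFrame(
        rows, columns=["d_low", "d_high", "n", "frac_w2s", "ci_low", "ci_high"]
    )


def relative_conversion_proportions(
    single_records, reference_records=None, reference_composition=None
) -> pd.DataFrame:
    """Observed single-SNP conversion-type proportions relative to a
    reference composition (nearest non-converted markers or multi-SNP
    events, which lack the single-site bias).

    ``reference_composition`` maps strand-equivalent pair labels to
    proportions; alternatively pass reference records.  Types absent
    from the reference are reported missing (NaN ratio).
    """
    obs = pd.Series(
        [r.pair_label for r in single_records], dtype="object"
    ).value_counts()
    if reference_composition is None:
        if reference_records is None:
            raise ValueError("need a reference composition or records")
        ref = pd.Series(
            [r.pair_label for r in reference_records], dtype="object"
        ).value_counts()
        reference_composition = (ref / ref.sum()).to_dict()
    labels = sorted(set(obs.index) | set(reference_composition))
    n = int(obs.sum())
    rows = []
    for lab in labels:
        k = int(obs.get(lab, 0))
        p_obs = k / n
        p_ref = reference_composition.get(lab, np.nan)
        ci = stats.binomtest(k, n, 0.5).proportion_ci(method="exact")
        ratio = p_obs / p_ref if (p_ref and np.isfinite(p_ref)) else np.nan
        rows.append(
            (lab, k, p_obs, p_ref, ratio, ci.low / p_ref if p_ref else np.nan,
             ci.high / p_ref if p_ref else np.nan)
        )
    return pd.DataFrame(
        rows,
        columns=["pair", "count", "obs_prop", "ref_prop", "ratio", "ci_low", "ci_high"],
    )


# ---------------------------------------------------------------------------
# Two-pathway model


@dataclass
class TwoPathwayModel:
    """GC-restoring pathway probability at Strong-recipient single
    mismatches."""

    p_block: float = 0.53

    def __post_init__(self):
        if not 0.0 <= self.p_block <= 1.0:
            raise ValueError("p_block must be in [0, 1]")


def expected_observed_bias(model) -> float:
    """Observed W->S fraction among surviving single-mismatch conversions.

    DSBs hit either homologue equally, so half of W/S heteroduplexes have
    a W recipient (always converted, W->S) and half an S recipient
    (converted S->W unless restored, probability 1-p):
    bias = 0.5 / (0.5 + 0.5(1-p)) = 1/(2-p).
    """
    p = model.p_block if isinstance(model, TwoPathwayModel) else float(model)
    if not 0.0 <= p <= 1.0:
        raise ValueError("p_block must be in [0, 1]")
    return 1.0 / (2.0 - p)


def p_block_from_bias(bias: float) -> float:
    """Inverse of :func:`expected_observed_bias`: p = 2 - 1/bias."""
    if bias <= 0:
        raise ValueError("bias must be positive")
    p = 2.0 - 1.0 / bias
    if p < 0:
        raise ValueError(f"bias {bias} <= 0.5 implies p_block <= 0")
    return p


def cap_bias_single_base(full_operation: float = 1.0) -> float:
    """Maximum observed bias if the GC-restoring mechanism acts at only
    one of the two Strong recipient bases (half of S-recipient
    configurations): effective block probability full_operation/2, so at
    most 1/(2-0.5) = 2/3 ~ 67%."""
    return expected_observed_bias(full_operation / 2.0)


def simulate_two_pathway(
    n: int, p_block: float, rng: np.random.Generator | None = None
):
    """Simulate single-mismatch W/S repairs; returns (n W->S observed,
    n observed conversions)."""
    if rng is None:
        rng = np.random.default_rng()
    recipient_w = rng.random(n) < 0.5
    restored = (~recipient_w) & (rng.random(n) < p_block)
    observed = ~restored
    return int((recipient_w & observed).sum()), int(observed.sum())


# ---------------------------------------------------------------------------
# Blocked markers in complex events


def exact_binomial_p(k: int, n: int, p0: float = 0.5) -> float:
    """Two-sided exact binomial p by the minimum-likelihood convention
    (sum of outcome probabilities <= that of the observed k); equals the
    doubled single tail at p0 = 0.5."""
    return float(stats.binomtest(k, n, p0).pvalue)


def blocked_marker_tally(complex_events, snp_map=None, records=None):
    """Tally internal non-converted markers of complex events by the
    S/W class of the recipient chromosome's base.

    Accepts either pre-classified ``records`` as (is_strong_recipient)
    booleans, or complex NCO calls plus the SNP map (recipient base at
    each internal unconverted SNP from the event's recipient homologue).
    Returns (k strong-recipient, n total, two-sided exact binomial p).
    """
    if records is not None:
        flags = [bool(b) for b in records]
    else:
        if not complex_events:
            raise ValueError("no complex events")
        flags = []
        for ev in complex_events:
            if not getattr(ev, "complex", False):
                continue
            if ev.recipient not in ("B6", "CAST"):
                continue
            cpos = snp_map.pos[ev.chrom]
            inside = np.arange(ev.snp_indices[0], ev.snp_indices[-1] + 1)
            unconverted = np.setdiff1d(inside, ev.snp_indices)
            for i in unconverted:
                al = (
                    snp_map.allele_b6[ev.chrom][i]
                    if ev.recipient == "B6"
                    else snp_map.allele_cast[ev.chrom][i]
                )
                flags.append(al in _STRONG)
    if not flags:
        raise ValueError("no internal non-converted markers found")
    k, n = int(np.sum(flags)), len(flags)
    return k, n, exact_binomial_p(k, n)


def required_dsb_ratio(
    observable_fraction_strand_aware: float,
    observable_fraction_strand_unaware: float,
    observed_total: float,
):
    """Total DSBs each repair model would require to produce the observed
    events: observed / observable fraction, per model."""
    for f in (observable_fraction_strand_aware, observable_fraction_strand_unaware):
        if not 0.0 < f <= 1.0:
            raise ValueError("observable fractions must be in (0, 1]")
    return (
        observed_total / observable_fraction_strand_aware,
        observed_total / observable_fraction_strand_unaware,
    )
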