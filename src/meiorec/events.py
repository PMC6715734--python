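"""CO/NCO event calling, filtering and classification.

Crossovers are background-state changes between successive SNPs.
Genotypes conflicting with their background are candidate converted
sites; a filter cascade removes founder-inconsistent sites, unbalanced
heterozygotes, low-depth homozygotes and excluded regions, and the
survivors are merged (2-kb gap rule) into NCO calls.  Events found in F5
animals are classified as inherited when an F4 parent carries an
identical event, and de novo otherwise; de novo events receive a
parent-of-origin where the pedigree is informative.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .hmm import STATES, states_per_snp

_CONCORDANT = {0: 0, 1: 1, 2: 2}  # state index -> concordant call code


# ---------------------------------------------------------------------------
# Data types


@dataclass
class CrossoverCall:
    sample_id: str
    chrom: str
    left_snp_pos: int
    right_snp_pos: int
    left_state: str
    right_state: str
    inheritance: str = "unknown"  # de_novo | inherited | unknown
    parent: str = "unknown"  # maternal | paternal | unknown
    complex: bool = False
    hotspot_id: Optional[int] = None

    def __post_init__(self):
        if self.left_snp_pos >= self.right_snp_pos:
            raise ValueError("crossover interval must have left < right")
        # direct BB<->CC switches imply an unresolved double event
        self.complex = {self.left_state, self.right_state} == {"BB", "CC"}

    @property
    def resolution(self) -> int:
        return self.right_snp_pos - self.left_snp_pos

    @property
    def signature(self):
        return (self.chrom, self.left_snp_pos, self.right_snp_pos)

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.left_snp_pos + self.right_snp_pos)


@dataclass
class NcoCall:
    sample_id: str
    chrom: str
    positions: np.ndarray  # converted SNP positions (bp)
    snp_indices: np.ndarray
    observed_calls: np.ndarray  # coded call at each converted site
    bg_state: str  # segment state context (consensus)
    recipient: str  # 'B6' | 'CAST' | 'unknown'
    donor_is_cast: np.ndarray  # per-site: donor allele is the CAST allele
    min_tract: tuple = (0, 0)  # [first, last converted]
    max_tract: tuple = (0, 0)  # (flanking unconverted SNPs)
    complex: bool = False
    inheritance: str = "unknown"
    parent: str = "unknown"
    hotspot_id: Optional[int] = None

    @property
    def n_converted(self) -> int:
        return len(self.positions)

    @property
    def signature(self):
        return (self.chrom, tuple(int(p) for p in self.positions))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.min_tract[0] + self.min_tract[1])


@dataclass
class FilterReport:
    """Ordered per-filter removal counts; conserves candidates."""

    filter_names: list
    input_count: int
    removed: dict
    surviving: int
    n_events: int = 0

    def check(self) -> bool:
        return self.input_count - sum(self.removed.values()) == self.surviving

    def to_frame(self) -> pd.DataFrame:
        rows = [("input", self.input_count)]
        rows += [(k, self.removed[k]) for k in self.filter_names]
        rows += [("surviving", self.surviving), ("events", self.n_events)]
        return pd.DataFrame(rows, columns=["stage", "count"])


@dataclass
class FilterConfig:
    """Thresholds of the false-positive filter cascade.

    The exact thresholds of the original study are not published in the
    main text; these defaults are documented and configurable.
    """

    balance_p_threshold: float = 0.01  # two-sided binomial allele balance
    min_het_minor: int = 2  # reads supporting the minor allele of a het
    min_hom_depth: int = 5
    min_hom_support: int = 5
    exclusion_regions: list = field(default_factory=list)  # (chrom, start, end)
    co_guard_bp: int = 0  # 0 disables the CO-proximity guard
    max_gap: int = 2000  # merge converted sites within this gap
    max_nco_segment_snps: int = 10  # dissolve shorter same-flank segments

    ORDER = (
        "founder",
        "allele_balance",
        "hom_depth",
        "excluded_region",
        "co_guard",
    )


# ---------------------------------------------------------------------------
# Segment post-processing and CO calling


def dissolve_short_segments(segments, max_snps: int = 10):
    """Merge short segments flanked by one identical state into the flanks.

    A background double switch over a handful of SNPs (e.g. BB->BC->BB)
    is an NCO-scale conversion, not two crossovers; dissolving the short
    middle segment lets its SNPs surface as conversion candidates while
    suppressing the spurious CO pair.  Short segments between two
    *different* flanking states are genuine transitions and are kept.
    """
    out = []
    bykey = {}
    for seg in segments:
        bykey.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sid, chrom), segs in bykey.items():
        segs = sorted(segs, key=lambda s: s.start_idx)
        changed = True
        while changed:
            changed = False
            for i in range(1, len(segs) - 1):
                mid = segs[i]
                if (
                    mid.n_snps <= max_snps
                    and segs[i - 1].state == segs[i + 1].state
                    and mid.state != segs[i - 1].state
                ):
                    left, right = segs[i - 1], segs[i + 1]
                    merged = type(left)(
                        sid,
                        chrom,
                        left.start_idx,
                        right.end_idx,
                        left.state,
                        (left.mean_posterior + right.mean_posterior) / 2.0,
                        left.start_pos,
                        right.end_pos,
                    )
                    segs = segs[: i - 1] + [merged] + segs[i + 2 :]
                    changed = True
                    break
        out.extend(segs)
    return out


def call_crossovers(segments) -> list:
    """One crossover call per adjacent segment pair with different states."""
    calls = []
    bykey = {}
    for seg in segments:
        bykey.setdefault((seg.sample_id, seg.chrom), []).append(seg)
    for (sid, chrom), segs in bykey.items():
        segs = sorted(segs, key=lambda s: s.start_idx)
        for a, b in zip(segs, segs[1:]):
            if a.state != b.state:
                calls.append(
                    CrossoverCall(
                        sid, chrom, a.end_pos, b.start_pos, a.state, b.state
                    )
                )
    return calls


# ---------------------------------------------------------------------------
# NCO candidates


def call_nco_candidates(genotypes, segments, snp_map) -> pd.DataFrame:
    """Emit every SNP whose call conflicts with its background state.

    Returns a DataFrame with one row per conflicting site:
    sample_id, chrom, snp_idx, pos, call, bg_state, recipient,
    donor_is_cast, depth, ad_b6, ad_cast.
    """
    state_arr = states_per_snp(segments, snp_map)
    rows = []
    for chrom in snp_map.chroms:
        st = state_arr[chrom]
        calls = genotypes.calls[chrom]
        assigned = st >= 0
        conflict = assigned & (calls >= 0) & (calls != st)
        idx = np.flatnonzero(conflict)
        if len(idx) == 0:
            continue
        st_i = st[idx]
        call_i = calls[idx]
        # recipient = homologue whose allele was replaced
        recipient = np.where(
            st_i == 0,
            "B6",  # BB background: a B6 haplotype was overwritten
            np.where(
                st_i == 2,
                "CAST",
                np.where(call_i == 0, "CAST", "B6"),  # BC: hom call
            ),
        )
        # donor allele = the allele gained relative to the background
        donor_is_cast = np.where(
            st_i == 0, True, np.where(st_i == 2, False, call_i == 2)
        )
        rows.append(
            pd.DataFrame(
                {
                    "sample_id": genotypes.sample_id,
                    "chrom": chrom,
                    "snp_idx": idx,
                    "pos": snp_map.pos[chrom][idx],
                    "call": call_i,
                    "bg_state": np.array(STATES)[st_i],
                    "recipient": recipient,
                    "donor_is_cast": donor_is_cast,
                    "depth": genotypes.depth[chrom][idx],
                    "ad_b6": genotypes.ad_b6[chrom][idx],
                    "ad_cast": genotypes.ad_cast[chrom][idx],
                }
            )
        )
    if not rows:
        return pd.DataFrame(
            columns=[
                "sample_id", "chrom", "snp_idx", "pos", "call", "bg_state",
                "recipient", "donor_is_cast", "depth", "ad_b6", "ad_cast",
            ]
        )
    return pd.concat(rows, ignore_index=True)


def _binom_balance_p(k: np.ndarray, n: np.ndarray) -> np.ndarray:
    """Vectorized two-sided exact binomial p at p0 = 1/2.

    Symmetric null, so the minimum-likelihood two-sided p equals the
    doubled smaller tail: P(|X - n/2| >= |k - n/2|).
    """
    k = np.asarray(k, dtype=np.int64)
    n = np.asarray(n, dtype=np.int64)
    lo = np.minimum(k, n - k)
    hi = np.maximum(k, n - k)
    p = stats.binom.cdf(lo, n, 0.5) + stats.binom.sf(hi - 1, n, 0.5)
    return np.minimum(p, 1.0)


def apply_filters(
    candidates: pd.DataFrame,
    all_genotypes: dict,
    snp_map,
    filter_config: FilterConfig | None = None,
    founder_roles: dict | None = None,
    crossovers: list | None = None,
):
    """Run the ordered false-positive filter cascade and merge survivors.

    Parameters
    ----------
    candidates : output of :func:`call_nco_candidates` (one sample or
        several concatenated; merging is per sample).
    all_genotypes : sample_id -> SampleGenotypes, must include the F0
        founders for the founder-consistency filter.
    founder_roles : founder sample_id -> 'B6' | 'CAST'.  Defaults to
        auto-detection of generation-F0 samples whose id mentions the
        strain.
    crossovers : CO calls used by the optional CO-proximity guard.

    Returns (list of NcoCall, FilterReport).
    """
    if filter_config is None:
        filter_config = FilterConfig()
    fc = filter_config
    if founder_roles is None:
        founder_roles = {}
        for sid, g in all_genotypes.items():
            if g.generation == "F0":
                founder_roles[sid] = "CAST" if "CAST" in sid.upper() else "B6"

    df = candidates.copy().reset_index(drop=True)
    input_count = len(df)
    removed = {name: 0 for name in FilterConfig.ORDER}
    alive = np.ones(len(df), dtype=bool)

    # (1) founder consistency: drop sites het or discordant in F0
    if founder_roles and len(df):
        bad_sites = {}
        for chrom in snp_map.chroms:
            bad = np.zeros(snp_map.n_sites(chrom), dtype=bool)
            for sid, role in founder_roles.items():
                calls = all_genotypes[sid].calls[chrom]
                expected = 0 if role == "B6" else 2
                bad |= calls == 1
                bad |= (calls >= 0) & (calls != expected) & (calls != 1)
            bad_sites[chrom] = bad
        hit = np.array(
            [bad_sites[c][i] for c, i in zip(df["chrom"], df["snp_idx"])]
        )
        removed["founder"] = int((alive & hit).sum())
        alive &= ~hit

    # (2) het candidates: two-sided binomial allele balance
    if len(df):
        is_het = df["call"].to_numpy() == 1
        with np.errstate(divide="ignore", invalid="ignore"):
            pvals = _binom_balance_p(
                df["ad_b6"].to_numpy(), df["depth"].to_numpy()
            )
        minor = np.minimum(df["ad_b6"].to_numpy(), df["ad_cast"].to_numpy())
        fail = is_het & (
            (pvals < fc.balance_p_threshold) | (minor < fc.min_het_minor)
        )
        removed["allele_balance"] = int((alive & fail).sum())
        alive &= ~fail

    # (3) hom candidates: depth and supporting-read thresholds
    if len(df):
        is_hom = (df["call"].to_numpy() == 0) | (df["call"].to_numpy() == 2)
        support = np.where(
            df["call"].to_numpy() == 0,
            df["ad_b6"].to_numpy(),
            df["ad_cast"].to_numpy(),
        )
        fail = is_hom & (
            (df["depth"].to_numpy() < fc.min_hom_depth)
            | (support < fc.min_hom_support)
        )
        removed["hom_depth"] = int((alive & fail).sum())
        alive &= ~fail

    # (4) configured exclusion regions
    if fc.exclusion_regions and len(df):
        fail = np.zeros(len(df), dtype=bool)
        for chrom, start, end in fc.exclusion_regions:
            fail |= (
                (df["chrom"].to_numpy() == chrom)
                & (df["pos"].to_numpy() >= start)
                & (df["pos"].to_numpy() < end)
            )
        removed["excluded_region"] = int((alive & fail).sum())
        alive &= ~fail

    # (5) optional guard distance around crossover breakpoints
    if fc.co_guard_bp > 0 and crossovers and len(df):
        fail = np.zeros(len(df), dtype=bool)
        for co in crossovers:
            fail |= (
                (df["sample_id"].to_numpy() == co.sample_id)
                & (df["chrom"].to_numpy() == co.chrom)
                & (df["pos"].to_numpy() >= co.left_snp_pos - fc.co_guard_bp)
                & (df["pos"].to_numpy() <= co.right_snp_pos + fc.co_guard_bp)
            )
        removed["co_guard"] = int((alive & fail).sum())
        alive &= ~fail

    surviving = df[alive]
    report = FilterReport(
        list(FilterConfig.ORDER), input_count, removed, int(alive.sum())
    )

    # (6) merge adjacent surviving candidates into NcoCall objects
    ncos = []
    for (sid, chrom), sub in surviving.groupby(["sample_id", "chrom"], sort=False):
        sub = sub.sort_values("pos")
        pos = sub["pos"].to_numpy()
        splits = np.flatnonzero(np.diff(pos) > fc.max_gap) + 1
        for block in np.split(np.arange(len(pos)), splits):
            b = sub.iloc[block]
            ncos.append(_make_nco(sid, chrom, b, snp_map))
    report.n_events = len(ncos)
    return ncos, report


def _make_nco(sid, chrom, block: pd.DataFrame, snp_map) -> NcoCall:
    idx = block["snp_idx"].to_numpy()
    pos = block["pos"].to_numpy()
    cpos = snp_map.pos[chrom]
    first, last = int(idx[0]), int(idx[-1])
    max_lo = int(cpos[first - 1]) if first > 0 else int(pos[0])
    max_hi = int(cpos[last + 1]) if last + 1 < len(cpos) else int(pos[-1])
    inside = np.arange(first, last + 1)
    is_complex = len(inside) > len(idx)  # unconverted SNP strictly inside
    recipients = block["recipient"].unique()
    recipient = recipients[0] if len(recipients) == 1 else "unknown"
    bgs = block["bg_state"].unique()
    bg = bgs[0] if len(bgs) == 1 else "mixed"
    return NcoCall(
        sample_id=sid,
        chrom=chrom,
        positions=pos.astype(np.int64),
        snp_indices=idx.astype(np.int64),
        observed_calls=block["call"].to_numpy(),
        bg_state=bg,
        recipient=str(recipient),
        donor_is_cast=block["donor_is_cast"].to_numpy(),
        min_tract=(int(pos[0]), int(pos[-1])),
        max_tract=(max_lo, max_hi),
        complex=bool(is_complex),
    )


# ---------------------------------------------------------------------------
# Classification


def classify_inheritance(child_events, parent_events_by_sample: dict, pedigree=None,
                         parents_of: dict | None = None):
    """Label child events de novo / inherited; deduplicate inherited ones.

    An event is inherited iff a parent carries an identical event (same
    converted SNP set for NCOs, same breakpoint interval for COs).
    Returns (annotated child events, list of distinct inherited events).
    """
    if parents_of is None:
        if pedigree is None:
            raise ValueError("need either a pedigree or a parents_of mapping")
        parents_of = {
            i.id: (i.mother_id, i.father_id) for i in pedigree.individuals.values()
        }
    parent_sigs = {
        sid: {e.signature for e in evs}
        for sid, evs in parent_events_by_sample.items()
    }
    seen_inherited = {}
    distinct = []
    for ev in child_events:
        parents = parents_of.get(ev.sample_id, (None, None))
        if parents == (None, None) or all(p is None for p in parents):
            ev.inheritance = "unknown"
            continue
        carriers = [
            p for p in parents if p in parent_sigs and ev.signature in parent_sigs[p]
        ]
        if carriers:
            ev.inheritance = "inherited"
            key = (tuple(sorted(parents)), ev.signature)
            if key not in seen_inherited:
                seen_inherited[key] = ev
                distinct.append(ev)
        else:
            ev.inheritance = "de_novo"
    return child_events, distinct


def de_novo_fraction(n_de_novo: int, n_inherited: int) -> float:
    """Fraction of called events arising in the sampled animal's parents'
    meioses (e.g. 821/(821+1384) = 0.372)."""
    total = n_de_novo + n_inherited
    if total == 0:
        return 0.0
    return n_de_novo / total


def assign_parent_of_origin(
    event,
    mother_genotypes,
    father_genotypes,
    mother_segments=None,
    father_segments=None,
    snp_map=None,
) -> str:
    """Parental origin of a de novo event.

    NCO: assigned to the heterozygous parent when the other parent is
    homozygous at every converted site; otherwise unknown.
    CO: rule-based haplotype tracer — the parent transmitting the
    recombinant haplotype must be able to supply the changed ancestry on
    both flanks while the other parent supplies the static one; assigned
    only when exactly one such assignment is feasible.
    """
    if isinstance(event, NcoCall):
        m_calls = [mother_genotypes.calls[event.chrom][i] for i in event.snp_indices]
        f_calls = [father_genotypes.calls[event.chrom][i] for i in event.snp_indices]
        m_het = all(c == 1 for c in m_calls)
        f_het = all(c == 1 for c in f_calls)
        m_hom = all(c in (0, 2) for c in m_calls)
        f_hom = all(c in (0, 2) for c in f_calls)
        if m_het and f_hom:
            return "maternal"
        if f_het and m_hom:
            return "paternal"
        return "unknown"
    # crossover
    if mother_segments is None or father_segments is None or snp_map is None:
        return "unknown"
    comp = _co_state_change(event.left_state, event.right_state)
    if comp is None:
        return "unknown"
    static, a_left, a_right = comp
    m_l = _state_at(mother_segments, event.chrom, event.left_snp_pos)
    m_r = _state_at(mother_segments, event.chrom, event.right_snp_pos)
    f_l = _state_at(father_segments, event.chrom, event.left_snp_pos)
    f_r = _state_at(father_segments, event.chrom, event.right_snp_pos)

    def can_supply(state, anc):
        if state is None:
            return True  # unknown background: not exclusionary
        return anc in {"BB": (0,), "BC": (0, 1), "CC": (1,)}[state]

    feas_mat = (
        can_supply(m_l, a_left)
        and can_supply(m_r, a_right)
        and can_supply(f_l, static)
        and can_supply(f_r, static)
    )
    feas_pat = (
        can_supply(f_l, a_left)
        and can_supply(f_r, a_right)
        and can_supply(m_l, static)
        and can_supply(m_r, static)
    )
    if feas_mat and not feas_pat:
        return "maternal"
    if feas_pat and not feas_mat:
        return "paternal"
    return "unknown"


def _co_state_change(left: str, right: str):
    """Decompose a state change into (static ancestry, left, right) of the
    recombinant haplotype; None for BB<->CC (no single-haplotype change)."""
    counts = {"BB": (0, 0), "BC": (0, 1), "CC": (1, 1)}
    l, r = counts[left], counts[right]
    for static in (0, 1):
        ll, rr = list(l), list(r)
        if static in ll and static in rr:
            ll.remove(static)
            rr.remove(static)
            if ll[0] != rr[0]:
                return static, ll[0], rr[0]
    return None


def _state_at(segments, chrom, pos):
    for seg in segments:
        if seg.chrom == chrom and seg.start_pos <= pos <= seg.end_pos:
            return seg.state
    return None


def assign_recipient_homologue(nco: NcoCall) -> str:
    """Recipient (cut) homologue of an NCO from background and calls."""
    return nco.recipient


# ---------------------------------------------------------------------------
# Hotspot overlap and validation arithmetic


def overlap_hotspots(events, dmc1_peaks: pd.DataFrame, h3k4_peaks: pd.DataFrame,
                     max_dist: int = 1000):
    """Assign each event to the nearest peak within ``max_dist`` bp.

    Peak tables need columns chrom/start/end/hotspot_id (BED-like,
    0-based half-open).  Events farther than ``max_dist`` from every
    peak of both assays stay unassigned.  Returns (events, fraction
    assigned).
    """
    peaks = pd.concat([dmc1_peaks, h3k4_peaks], ignore_index=True)
    bychrom = {
        c: sub.sort_values("start") for c, sub in peaks.groupby("chrom")
    }
    n_assigned = 0
    for ev in events:
        if isinstance(ev, NcoCall):
            lo, hi = ev.min_tract
        else:
            lo, hi = ev.left_snp_pos, ev.right_snp_pos
        sub = bychrom.get(ev.chrom)
        ev.hotspot_id = None
        if sub is None or len(sub) == 0:
            continue
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        dist = np.maximum(starts - hi, 0) + np.maximum(lo - ends, 0)
        j = int(np.argmin(dist))
        if dist[j] < max_dist:
            ev.hotspot_id = int(sub["hotspot_id"].iloc[j])
            n_assigned += 1
    frac = n_assigned / len(events) if events else float("nan")
    return events, frac


def estimate_validated_fraction(
    frac_in_hotspot: float, confirm_rate_in: float, confirm_rate_out: float
) -> float:
    """Overall fraction of detected NCOs estimated to be genuine.

    Combines the hotspot-overlap fraction with the in- and out-of-hotspot
    confirmation rates:  f*c_in + (1-f)*c_out.
    """
    for v in (frac_in_hotspot, confirm_rate_in, confirm_rate_out):
        if not 0.0 <= v <= 1.0:
            raise ValueError("all inputs must be in [0, 1]")
    return frac_in_hotspot * confirm_rate_in + (1.0 - frac_in_hotspot) * confirm_rate_out
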