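"""End-to-end drivers: per-sample calling and truth-recovery metrics."""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import (
    FilterConfig,
    apply_filters,
    call_crossovers,
    call_nco_candidates,
    classify_inheritance,
    dissolve_short_segments,
)
from .hmm import HmmParams, infer_background


@dataclass
class SampleCalls:
    sample_id: str
    segments: list
    crossovers: list
    ncos: list
    report: object


def call_sample(
    genotypes,
    snp_map,
    all_genotypes: dict,
    hmm_params: HmmParams | None = None,
    filter_config: FilterConfig | None = None,
    founder_roles: dict | None = None,
) -> SampleCalls:
    """Background inference, CO calling, NCO calling for one sample."""
    if hmm_params is None:
        hmm_params = HmmParams()
    if filter_config is None:
        filter_config = FilterConfig()
    segments = infer_background(genotypes, snp_map, hmm_params)
    segments = dissolve_short_segments(
        segments, filter_config.max_nco_segment_snps
    )
    cos = call_crossovers(segments)
    candidates = call_nco_candidates(genotypes, segments, snp_map)
    ncos, report = apply_filters(
        candidates,
        all_genotypes,
        snp_map,
        filter_config,
        founder_roles=founder_roles,
        crossovers=cos,
    )
    return SampleCalls(genotypes.sample_id, segments, cos, ncos, report)


def call_cohort(
    genotypes: dict,
    snp_map,
    sample_ids=None,
    hmm_params: HmmParams | None = None,
    filter_config: FilterConfig | None = None,
    founder_roles: dict | None = None,
) -> dict:
    """Run :func:`call_sample` for each requested sample."""
    if sample_ids is None:
        sample_ids = [
            sid for sid, g in genotypes.items() if g.generation != "F0"
        ]
    return {
        sid: call_sample(
            genotypes[sid], snp_map, genotypes, hmm_params, filter_config,
            founder_roles,
        )
        for sid in sample_ids
    }


def hotspot_peaks(hotspots: pd.DataFrame, half_width: int = 500) -> pd.DataFrame:
    """BED-like peak intervals (0-based half-open) around hotspot centers."""
    return pd.DataFrame(
        {
            "chrom": hotspots["chrom"],
            "start": hotspots["center"] - half_width,
            "end": hotspots["center"] + half_width,
            "hotspot_id": hotspots["hotspot_id"],
        }
    )


# ---------------------------------------------------------------------------
# Truth comparison


@dataclass
class RecoveryMetrics:
    nco_recall: float
    nco_precision: float
    co_recall: float
    co_precision: float
    n_truth_nco: int
    n_truth_co: int
    n_called_nco_sites: int
    n_called_co: int


def _truth_events_for(pedigree, sample_id):
    ind = pedigree.individuals[sample_id]
    evs = []
    for parent in (ind.mother_id, ind.father_id):
        if parent is not None:
            evs.extend(pedigree.events.get(f"{parent}>{sample_id}", []))
    return evs


def _co_recoverable(pedigree, sample_id, ev):
    """A truth CO is marker-visible iff the diploid background state
    differs between the SNPs flanking its breakpoint.

    Two crossovers from the two parental meioses falling in the same
    inter-SNP gap can cancel at the diploid level; no caller can see
    them, so they do not enter the recall denominator.
    """
    ind = pedigree.individuals[sample_id]
    pos = pedigree.snp_map.pos[ev.chrom]
    i = np.searchsorted(pos, ev.breakpoint, side="right")
    if i == 0 or i >= len(pos):
        return False
    bg = ind.background_state(ev.chrom)
    return bg[i - 1] != bg[i]


def _expand_left(snp_map, co):
    """Left call boundary widened by one SNP: posterior decoding places a
    background switch to within one inter-SNP gap."""
    pos = snp_map.pos[co.chrom]
    i = np.searchsorted(pos, co.left_snp_pos) - 1
    return pos[i] if i >= 0 else co.left_snp_pos


def _expand_right(snp_map, co):
    pos = snp_map.pos[co.chrom]
    i = np.searchsorted(pos, co.right_snp_pos, side="right")
    return pos[i] if i < len(pos) else co.right_snp_pos


def truth_recovery(
    pedigree, calls_by_sample: dict, interaction_bp: float = 0.0
) -> RecoveryMetrics:
    """Site-containment recall/precision of called events against truth.

    An NCO truth event is *visible* at a site when the child's diploid
    truth genotype conflicts with its diploid ancestry background (a
    conversion cancelled by the other parental meiosis carries no
    signal).  An event (restricted to those with >= 1 visible site) is
    recovered when all its visible converted positions appear among the
    sample's called converted positions; called-site precision requires
    every called converted position to be a genuine conversion signal
    (truth genotype conflicting with truth background).  A truth CO
    (restricted to marker-visible ones, see :func:`_co_recoverable`) is
    recovered when some called breakpoint interval contains it; a called
    CO is correct when its interval contains a truth breakpoint.

    ``interaction_bp`` > 0 excludes interacting events from both
    denominators: a conversion within that distance of a crossover
    breakpoint of the same sample is indistinguishable from a shifted
    breakpoint (and vice versa), an ambiguity of the data rather than of
    the caller.  At study scale such collisions are vanishingly rare;
    the scaled synthetic genome concentrates events onto far fewer
    hotspots, so the joint recovery test masks them out explicitly.
    """
    n_truth_nco = n_rec_nco = 0
    n_truth_co = n_rec_co = 0
    n_called_sites = n_good_sites = 0
    n_called_co = n_good_co = 0
    for sid, calls in calls_by_sample.items():
        ind = pedigree.individuals[sid]
        truth = _truth_events_for(pedigree, sid)
        conflict = {
            c: ind.truth_genotypes(c) != ind.background_state(c)
            for c in pedigree.snp_map.chroms
        }
        all_bks = {}
        vis_by_event = []
        for ev in truth:
            if ev.kind == "CO":
                all_bks.setdefault(ev.chrom, []).append(float(ev.breakpoint))
        vis_sites_all = {}
        for ev in truth:
            if ev.kind != "NCO" or ev.informative is None or not len(ev.informative):
                vis_by_event.append(None)
                continue
            vis = ev.informative[conflict[ev.chrom][ev.informative]]
            vis_by_event.append(pedigree.snp_map.pos[ev.chrom][vis])
            vis_sites_all.setdefault(ev.chrom, []).extend(
                float(p) for p in pedigree.snp_map.pos[ev.chrom][vis]
            )

        def near(values, x, w):
            return any(abs(v - x) <= w for v in values)

        called_sites = {}
        for nco in calls.ncos:
            called_sites.setdefault(nco.chrom, set()).update(
                int(p) for p in nco.positions
            )
        truth_bks = {}
        for ev, vis_pos in zip(truth, vis_by_event):
            if ev.kind == "NCO":
                if vis_pos is None or len(vis_pos) == 0:
                    continue
                if interaction_bp and near(
                    all_bks.get(ev.chrom, []), float(np.mean(vis_pos)),
                    interaction_bp + (vis_pos.max() - vis_pos.min()) / 2,
                ):
                    continue
                n_truth_nco += 1
                if all(
                    int(p) in called_sites.get(ev.chrom, set()) for p in vis_pos
                ):
                    n_rec_nco += 1
            else:
                if not _co_recoverable(pedigree, sid, ev):
                    continue
                bk = float(ev.breakpoint)
                if interaction_bp and (
                    near(vis_sites_all.get(ev.chrom, []), bk, interaction_bp)
                    or sum(
                        1 for b in all_bks.get(ev.chrom, [])
                        if abs(b - bk) <= interaction_bp
                    ) > 1
                ):
                    continue
                n_truth_co += 1
                truth_bks.setdefault(ev.chrom, []).append(bk)
                if any(
                    co.chrom == ev.chrom
                    and _expand_left(pedigree.snp_map, co) <= bk
                    <= _expand_right(pedigree.snp_map, co)
                    for co in calls.crossovers
                ):
                    n_rec_co += 1
        for chrom, sites in called_sites.items():
            conflict_pos = set(
                int(p) for p in pedigree.snp_map.pos[chrom][conflict[chrom]]
            )
            for p in sites:
                if interaction_bp and near(all_bks.get(chrom, []), p, interaction_bp):
                    continue
                n_called_sites += 1
                if p in conflict_pos:
                    n_good_sites += 1
        for co in calls.crossovers:
            if interaction_bp and near(
                vis_sites_all.get(co.chrom, []), co.midpoint,
                interaction_bp + co.resolution / 2,
            ):
                continue
            n_called_co += 1
            lo = _expand_left(pedigree.snp_map, co)
            hi = _expand_right(pedigree.snp_map, co)
            if any(lo <= bk <= hi for bk in all_bks.get(co.chrom, [])):
                n_good_co += 1
    return RecoveryMetrics(
        nco_recall=n_rec_nco / n_truth_nco if n_truth_nco else float("nan"),
        nco_precision=n_good_sites / n_called_sites if n_called_sites else float("nan"),
        co_recall=n_rec_co / n_truth_co if n_truth_co else float("nan"),
        co_precision=n_good_co / n_called_co if n_called_co else float("nan"),
        n_truth_nco=n_truth_nco,
        n_truth_co=n_truth_co,
        n_called_nco_sites=n_called_sites,
        n_called_co=n_called_co,
    )


def events_to_table(calls_by_sample: dict) -> pd.DataFrame:
    """Flatten called events to one DataFrame (positions comma-joined)."""
    rows = []
    for sid, calls in calls_by_sample.items():
        for co in calls.crossovers:
            rows.append(
                {
                    "sample_id": sid,
                    "kind": "CO",
                    "chrom": co.chrom,
                    "start": co.left_snp_pos,
                    "end": co.right_snp_pos,
                    "positions": "",
                    "recipient": "unknown",
                    "inheritance": co.inheritance,
                    "parent": co.parent,
                    "complex": co.complex,
                    "hotspot_id": co.hotspot_id,
                }
            )
        for nco in calls.ncos:
            rows.append(
                {
                    "sample_id": sid,
                    "kind": "NCO",
                    "chrom": nco.chrom,
                    "start": nco.min_tract[0],
                    "end": nco.min_tract[1],
                    "positions": ",".join(str(int(p)) for p in nco.positions),
                    "recipient": nco.recipient,
                    "inheritance": nco.inheritance,
                    "parent": nco.parent,
                    "complex": nco.complex,
                    "hotspot_id": nco.hotspot_id,
                }
            )
    return pd.DataFrame(rows)
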