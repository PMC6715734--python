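"""Detection-power estimation by genotype splicing.

NCO tracts are simulated at hotspots (sampled proportional to H3K4me3
enrichment), with centers drawn from the motif-displacement distribution
and exponential lengths over a grid of mean tract lengths.  For each
tract a recipient animal is chosen; a donor animal whose genotype at the
tract SNPs matches the post-conversion state is selected and its
call-level information (GT/DP/AD) copied onto the recipient — splicing
downstream of variant calling, so the spliced candidate carries
realistic depths.  The full filter cascade is then applied; power is
the fraction of tracts containing >= 1 SNP that survive filtering.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .events import FilterConfig, _binom_balance_p
from .hmm import states_per_snp

DEFAULT_GRID = tuple(range(10, 101, 10)) + tuple(range(150, 301, 50))


@dataclass
class PowerResult:
    """Per-tract-mean detection power with Monte-Carlo errors."""

    grid: np.ndarray  # mean tract lengths (bp)
    n_simulated: np.ndarray
    n_with_snp: np.ndarray
    n_surviving: np.ndarray
    n_no_donor: np.ndarray

    @property
    def power(self) -> np.ndarray:
        with np.errstate(invalid="ignore", divide="ignore"):
            return self.n_surviving / self.n_with_snp

    @property
    def mc_se(self) -> np.ndarray:
        p = self.power
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.sqrt(p * (1 - p) / self.n_with_snp)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "mean_tract_bp": self.grid,
                "n_simulated": self.n_simulated,
                "n_with_snp": self.n_with_snp,
                "n_surviving": self.n_surviving,
                "n_no_donor": self.n_no_donor,
                "power": self.power,
                "mc_se": self.mc_se,
            }
        )


def _post_conversion_call(bg_state: int, donor_allele_cast: bool) -> int:
    """Coded call a conversion produces on the given background."""
    if bg_state == 0:  # BB: gains a CAST allele -> het
        return 1
    if bg_state == 2:  # CC: gains a B6 allele -> het
        return 1
    # BC: one homologue overwritten -> hom of the donor allele
    return 2 if donor_allele_cast else 0


def run_power_simulation(
    hotspots: pd.DataFrame,
    snp_map,
    genotypes: dict,
    backgrounds: dict,
    filter_config: FilterConfig | None = None,
    grid=DEFAULT_GRID,
    n_hotspot_draws: int = 2000,
    center_sd: float = 200.0,
    recipient_ids=None,
    founder_bad_sites: dict | None = None,
    enrichment_col: str = "heat",
    rng: np.random.Generator | None = None,
    filters_enabled: bool = True,
) -> PowerResult:
    """Spliced-genotype power simulation over a grid of tract means.

    ``genotypes``: sample_id -> SampleGenotypes; ``backgrounds``:
    sample_id -> background segments (from :func:`infer_background`).
    Tracts with zero SNPs are never counted as potentially detectable;
    tracts with no eligible donor are skipped and counted.
    """
    grid = np.asarray(list(grid), dtype=float)
    if len(grid) == 0:
        raise ValueError("grid must be nonempty")
    if rng is None:
        rng = np.random.default_rng()
    if filter_config is None:
        filter_config = FilterConfig()
    fc = filter_config
    if recipient_ids is None:
        recipient_ids = [
            sid for sid, g in genotypes.items() if g.generation != "F0"
        ]
    state_by_sample = {
        sid: states_per_snp(backgrounds[sid], snp_map) for sid in genotypes
        if sid in backgrounds
    }
    heats = hotspots[enrichment_col].to_numpy(dtype=float)
    p_hot = heats / heats.sum()
    hchrom = hotspots["chrom"].to_numpy()
    hmotif = hotspots["motif_center"].to_numpy()

    n_sim = np.zeros(len(grid), dtype=int)
    n_snp = np.zeros(len(grid), dtype=int)
    n_surv = np.zeros(len(grid), dtype=int)
    n_nodonor = np.zeros(len(grid), dtype=int)

    donor_pool = list(genotypes)
    for gi, mean in enumerate(grid):
        picks = rng.choice(len(hotspots), size=n_hotspot_draws, p=p_hot)
        centers = hmotif[picks] + rng.normal(0, center_sd, size=n_hotspot_draws)
        lengths = np.maximum(1.0, rng.exponential(mean, size=n_hotspot_draws))
        rec_pick = rng.choice(len(recipient_ids), size=n_hotspot_draws)
        n_sim[gi] = n_hotspot_draws
        for t in range(n_hotspot_draws):
            chrom = hchrom[picks[t]]
            cpos = snp_map.pos[chrom]
            lo = np.searchsorted(cpos, centers[t] - lengths[t] / 2, "left")
            hi = np.searchsorted(cpos, centers[t] + lengths[t] / 2, "right")
            if hi <= lo:
                continue
            n_snp[gi] += 1
            idx = np.arange(lo, hi)
            rid = recipient_ids[rec_pick[t]]
            rstates = state_by_sample[rid][chrom][idx]
            if np.any(rstates < 0):
                n_nodonor[gi] += 1
                continue
            # donor allele: at BB the donor is CAST, at CC B6; at BC pick
            # the cut homologue by a fair coin (both are valid repairs)
            donor_cast = np.where(
                rstates == 0, True, np.where(rstates == 2, False, rng.random() < 0.5)
            )
            target = np.array(
                [
                    _post_conversion_call(s, dc)
                    for s, dc in zip(rstates, donor_cast)
                ],
                dtype=np.int8,
            )
            donor = _find_donor(
                donor_pool, genotypes, rid, chrom, idx, target, rng
            )
            if donor is None:
                n_nodonor[gi] += 1
                continue
            if not filters_enabled:
                n_surv[gi] += 1
                continue
            if _splice_survives(
                genotypes[donor], chrom, idx, target, fc, founder_bad_sites
            ):
                n_surv[gi] += 1
    return PowerResult(grid, n_sim, n_snp, n_surv, n_nodonor)


def _find_donor(pool, genotypes, recipient_id, chrom, idx, target, rng):
    """A sample whose calls at the tract SNPs equal the post-conversion
    genotype (uniform among eligible donors)."""
    order = rng.permutation(len(pool))
    for j in order:
        sid = pool[j]
        if sid == recipient_id:
            continue
        calls = genotypes[sid].calls[chrom][idx]
        if np.array_equal(calls, target):
            return sid
    return None


def _splice_survives(donor_g, chrom, idx, target, fc: FilterConfig,
                     founder_bad_sites) -> bool:
    """Apply the per-site filter cascade to the spliced candidate sites;
    the tract survives if at least one converted site survives."""
    depth = donor_g.depth[chrom][idx]
    adb = donor_g.ad_b6[chrom][idx]
    adc = donor_g.ad_cast[chrom][idx]
    alive = np.ones(len(idx), dtype=bool)
    if founder_bad_sites is not None:
        alive &= ~founder_bad_sites[chrom][idx]
    het = target == 1
    if het.any():
        p = _binom_balance_p(adb[het], depth[het])
        minor = np.minimum(adb[het], adc[het])
        ok = (p >= fc.balance_p_threshold) & (minor >= fc.min_het_minor)
        alive[np.flatnonzero(het)[~ok]] = False
    hom = ~het
    if hom.any():
        support = np.where(target[hom] == 0, adb[hom], adc[hom])
        bad = (depth[hom] < fc.min_hom_depth) | (support < fc.min_hom_support)
        alive[np.flatnonzero(hom)[bad]] = False
    return bool(alive.any())


def detection_weights(
    hotspots: pd.DataFrame,
    snp_map,
    tract_mean_bp: float,
    center_sd: float = 200.0,
    survival_given_snp: float = 1.0,
    n_mc: int = 50,
    rng: np.random.Generator | None = None,
) -> pd.Series:
    """Per-hotspot NCO detection weight, normalized to mean 1.

    The weight is the Monte-Carlo probability that an exponential tract
    placed at the hotspot contains >= 1 SNP (a function of the local SNP
    configuration and the tract model), times a global filter-survival
    factor.  Hotspots with no nearby SNPs get weight ~ 0.
    """
    if rng is None:
        rng = np.random.default_rng()
    probs = np.zeros(len(hotspots))
    for i, (_, row) in enumerate(hotspots.iterrows()):
        cpos = snp_map.pos[row["chrom"]]
        centers = row["motif_center"] + rng.normal(0, center_sd, size=n_mc)
        lengths = np.maximum(1.0, rng.exponential(tract_mean_bp, size=n_mc))
        lo = np.searchsorted(cpos, centers - lengths / 2, "left")
        hi = np.searchsorted(cpos, centers + lengths / 2, "right")
        probs[i] = np.mean(hi > lo) * survival_given_snp
    if probs.sum() <= 0:
        raise ValueError("zero total detection weight")
    w = probs / probs.mean()
    return pd.Series(w, index=hotspots["hotspot_id"].to_numpy(), name="weight")
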