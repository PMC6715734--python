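"""Synthetic cross generator.

Produces founder SNP maps, hotspot tables, pedigrees with phased truth
genomes, per-sample genotype calls with depths and allelic depths, and
allele-assignable ChIP count data, so every downstream stage of the
pipeline can be tested without external data.

Coordinates are 1-based bp internally for SNP positions (matching VCF);
BED output is 0-based half-open.

Haplotypes track two int8 arrays per chromosome: ``alleles`` (0 = B6
founder allele, 1 = CAST founder allele — what sequencing sees) and
``ancestry`` (0 = descends from the B6 founder chromosome, 1 = CAST —
what the background HMM infers).  The two differ exactly at
gene-converted sites.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
import pandas as pd

from .config import SimConfig

_BASES = np.array(["A", "C", "G", "T"])
_STRONG = frozenset("GC")

HOM_B6, HET, HOM_CAST, MISSING = 0, 1, 2, -1


# ---------------------------------------------------------------------------
# SNP map


class SnpMap:
    """Ordered biallelic founder-diagnostic SNPs with S/W base classes.

    Parameters
    ----------
    chrom_lengths : dict chrom -> length (bp)
    pos : dict chrom -> strictly increasing int array of 1-based positions
    allele_b6, allele_cast : dict chrom -> arrays of single bases
    """

    def __init__(self, chrom_lengths, pos, allele_b6, allele_cast):
        self.chrom_lengths = dict(chrom_lengths)
        self.chroms = list(self.chrom_lengths)
        self.pos = {c: np.asarray(pos[c], dtype=np.int64) for c in self.chroms}
        self.allele_b6 = {c: np.asarray(allele_b6[c]) for c in self.chroms}
        self.allele_cast = {c: np.asarray(allele_cast[c]) for c in self.chroms}
        for c in self.chroms:
            p = self.pos[c]
            if len(p) and np.any(np.diff(p) <= 0):
                raise ValueError(f"positions on {c} not strictly increasing")
            if np.any(self.allele_b6[c] == self.allele_cast[c]):
                raise ValueError(f"monomorphic site on {c}")

    def n_sites(self, chrom=None) -> int:
        if chrom is not None:
            return len(self.pos[chrom])
        return sum(len(self.pos[c]) for c in self.chroms)

    def is_strong(self, chrom, which) -> np.ndarray:
        """Boolean array: allele of ``which`` ('b6' or 'cast') is G or C."""
        al = self.allele_b6[chrom] if which == "b6" else self.allele_cast[chrom]
        return np.isin(al, ["G", "C"])

    def to_dataframe(self) -> pd.DataFrame:
        frames = []
        for c in self.chroms:
            frames.append(
                pd.DataFrame(
                    {
                        "chrom": c,
                        "pos": self.pos[c],
                        "allele_b6": self.allele_b6[c],
                        "allele_cast": self.allele_cast[c],
                    }
                )
            )
        df = pd.concat(frames, ignore_index=True)
        df["class_b6"] = np.where(df["allele_b6"].isin(list("GC")), "S", "W")
        df["class_cast"] = np.where(df["allele_cast"].isin(list("GC")), "S", "W")
        return df

    def write_tsv(self, path) -> None:
        self.to_dataframe().to_csv(path, sep="\t", index=False)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, chrom_lengths) -> "SnpMap":
        pos, b6, cast = {}, {}, {}
        for c, sub in df.groupby("chrom", sort=False):
            pos[c] = sub["pos"].to_numpy()
            b6[c] = sub["allele_b6"].to_numpy()
            cast[c] = sub["allele_cast"].to_numpy()
        return cls(chrom_lengths, pos, b6, cast)


def simulate_snp_map(config: SimConfig, rng: np.random.Generator) -> SnpMap:
    """Draw a founder SNP map with i.i.d. geometric inter-SNP gaps.

    The gap mean is ``config.snp_spacing_mean`` so a 17-Mb chromosome at
    the default spacing carries ~100,000 SNPs.
    """
    pos, b6, cast = {}, {}, {}
    lengths = dict(zip(config.chroms, config.chrom_lengths))
    for chrom, length in lengths.items():
        # oversample gaps, then trim to chromosome length
        n_guess = int(length / config.snp_spacing_mean * 1.1) + 100
        p = min(1.0, 1.0 / config.snp_spacing_mean)
        positions = []
        last = 0
        while True:
            gaps = rng.geometric(p, size=n_guess)
            cum = last + np.cumsum(gaps)
            inside = cum[cum <= length]
            positions.append(inside)
            if len(inside) < len(cum):
                break
            last = cum[-1]
        ppos = np.concatenate(positions)
        n = len(ppos)
        a_b6 = rng.integers(0, 4, size=n)
        a_cast = (a_b6 + rng.integers(1, 4, size=n)) % 4
        pos[chrom] = ppos
        b6[chrom] = _BASES[a_b6]
        cast[chrom] = _BASES[a_cast]
    return SnpMap(lengths, pos, b6, cast)


# ---------------------------------------------------------------------------
# Hotspots


def simulate_hotspots(
    config: SimConfig, snp_map: SnpMap, rng: np.random.Generator
) -> pd.DataFrame:
    """Place PRDM9 hotspots with heavy-tailed heats and binding ratios.

    Returns a DataFrame with columns: ``hotspot_id, chrom, center, heat,
    x, controlling_allele, asymmetric, motif_center, motif_start,
    motif_end, motif_strand, motif_posterior, motif_disrupted``.

    Heats are lognormal with log-scale sd ``config.heat_shape``; at the
    default (1.1) the hottest sixth of hotspots carries more than half
    of the total heat while no single hotspot dominates.  A fraction ``frac_asymmetric`` of hotspots receives a
    binding ratio x near 0 or 1 and (with probability
    ``motif_disrupted_rate_asym``) a polymorphism inside its motif.
    """
    if snp_map.n_sites() == 0:
        raise ValueError("snp_map is empty")
    lengths = snp_map.chrom_lengths
    total = sum(lengths.values())
    capacity = sum(length // 2000 for length in lengths.values())
    if config.n_hotspots > capacity:
        raise ValueError(
            f"{config.n_hotspots} hotspots exceed genome capacity "
            f"({capacity}) at 2-kb spacing"
        )
    margin = 5000
    rows = []
    n_per = rng.multinomial(
        config.n_hotspots, [lengths[c] / total for c in snp_map.chroms]
    )
    hid = 0
    for chrom, n_c in zip(snp_map.chroms, n_per):
        length = lengths[chrom]
        lo, hi = margin, max(margin + 1, length - margin)
        centers = np.sort(rng.integers(lo, hi, size=n_c))
        # enforce >= 2 kb spacing by nudging/redrawing collisions
        for _ in range(200):
            gaps = np.diff(centers)
            bad = np.where(gaps < 2000)[0]
            if len(bad) == 0:
                break
            centers[bad + 1] = rng.integers(lo, hi, size=len(bad))
            centers = np.sort(centers)
        heats = rng.lognormal(0.0, config.heat_shape, size=n_c)
        asym = rng.random(n_c) < config.frac_asymmetric
        x = np.where(
            asym,
            np.where(
                rng.random(n_c) < 0.5,
                rng.beta(1.5, 30.0, size=n_c),
                1.0 - rng.beta(1.5, 30.0, size=n_c),
            ),
            rng.beta(30.0, 30.0, size=n_c),
        )
        ctrl = np.where(
            rng.random(n_c) < config.frac_cast_controlled, "Cast", "Hum"
        )
        disrupted = np.where(
            asym,
            rng.random(n_c) < config.motif_disrupted_rate_asym,
            rng.random(n_c) < config.motif_disrupted_rate_sym,
        )
        posterior = 1.0 - rng.beta(1.0, 60.0, size=n_c)  # mostly > 0.99
        strand = np.where(rng.random(n_c) < 0.5, "+", "-")
        cpos = snp_map.pos[chrom]
        half = config.motif_width // 2
        for i in range(n_c):
            want = centers[i] + int(round(rng.normal(0, 100)))
            want = int(np.clip(want, centers[i] - 900, centers[i] + 900))
            mcenter = _place_motif(
                cpos, want, half, bool(disrupted[i]), centers[i]
            )
            rows.append(
                (
                    hid,
                    chrom,
                    int(centers[i]),
                    float(heats[i]),
                    float(np.clip(x[i], 0.0, 1.0)),
                    ctrl[i],
                    bool(asym[i]),
                    int(mcenter),
                    int(mcenter - half),
                    int(mcenter + half),
                    strand[i],
                    float(posterior[i]),
                    bool(disrupted[i]),
                )
            )
            hid += 1
    return pd.DataFrame(
        rows,
        columns=[
            "hotspot_id",
            "chrom",
            "center",
            "heat",
            "x",
            "controlling_allele",
            "asymmetric",
            "motif_center",
            "motif_start",
            "motif_end",
            "motif_strand",
            "motif_posterior",
            "motif_disrupted",
        ],
    )


def _place_motif(cpos, want, half, disrupted, center):
    """Center the motif on a SNP when disrupted, in a SNP-free gap otherwise."""
    i = np.searchsorted(cpos, want)
    if disrupted:
        # snap to the nearest SNP (if any within 1 kb of the hotspot center)
        cand = []
        if i < len(cpos):
            cand.append(cpos[i])
        if i > 0:
            cand.append(cpos[i - 1])
        if cand:
            best = min(cand, key=lambda p: abs(p - want))
            if abs(best - center) <= 1000 - half:
                return int(best)
        return want
    # look for a gap wide enough to hold the motif without a SNP
    for j in range(max(0, i - 3), min(len(cpos) - 1, i + 3)):
        left, right = cpos[j], cpos[j + 1]
        if right - left > 2 * half + 2:
            mid = (left + right) // 2
            if abs(mid - center) <= 1000 - half:
                return int(mid)
    return want


# ---------------------------------------------------------------------------
# Genomes, gametes, meiosis


@dataclass
class Haplotype:
    """One chromosome set: per-chrom allele and ancestry arrays (int8)."""

    alleles: dict
    ancestry: dict

    def copy(self) -> "Haplotype":
        return Haplotype(
            {c: a.copy() for c, a in self.alleles.items()},
            {c: a.copy() for c, a in self.ancestry.items()},
        )


def founder_haplotype(snp_map: SnpMap, which: int) -> Haplotype:
    """Fully inbred founder haplotype (0 = B6, 1 = CAST)."""
    return Haplotype(
        {c: np.full(snp_map.n_sites(c), which, dtype=np.int8) for c in snp_map.chroms},
        {c: np.full(snp_map.n_sites(c), which, dtype=np.int8) for c in snp_map.chroms},
    )


@dataclass
class TrueEvent:
    """A homologue-templated DSB repair on a transmitted gamete."""

    meiosis_id: str
    kind: str  # 'CO' or 'NCO'
    chrom: str
    hotspot_id: Optional[int]
    recipient: Optional[str]  # 'B6' or 'CAST' (ancestry of the cut chromatid)
    breakpoint: Optional[int] = None  # CO only
    tract_start: Optional[int] = None  # NCO only
    tract_end: Optional[int] = None
    snp_indices: Optional[np.ndarray] = None  # SNPs inside the tract
    informative: Optional[np.ndarray] = None  # subset where donor != recipient


@dataclass
class Individual:
    id: str
    generation: str
    sex: str
    mother_id: Optional[str]
    father_id: Optional[str]
    hap_mat: Haplotype
    hap_pat: Haplotype

    def truth_genotypes(self, chrom) -> np.ndarray:
        """0/1/2 copies of the CAST allele at each SNP."""
        return (
            self.hap_mat.alleles[chrom].astype(np.int8)
            + self.hap_pat.alleles[chrom].astype(np.int8)
        )

    def background_state(self, chrom) -> np.ndarray:
        """True ancestry state per SNP: 0=BB, 1=BC, 2=CC."""
        return (
            self.hap_mat.ancestry[chrom].astype(np.int8)
            + self.hap_pat.ancestry[chrom].astype(np.int8)
        )


def simulate_meiosis(
    parent: Individual,
    hotspots: pd.DataFrame,
    snp_map: SnpMap,
    config: SimConfig,
    rng: np.random.Generator,
    meiosis_id: str = "meiosis",
    heat_scale: float = 1.0,
):
    """Produce one transmitted gamete and its truth events.

    The DSB count is Poisson with mean ``dsb_per_meiosis_mean``; each DSB
    is assigned a hotspot with probability proportional to heat times the
    PRDM9 binding of the recipient homologue; a fraction ``co_fraction``
    resolve as crossovers (at least one per chromosome when
    ``obligate_co``), the rest as NCO conversion tracts with exponential
    lengths (allele-specific means) centered near the hotspot motif.
    """
    if len(hotspots) == 0:
        raise ValueError("hotspot list is empty")
    heats = hotspots["heat"].to_numpy() * heat_scale
    hchrom = hotspots["chrom"].to_numpy()
    hcenter = hotspots["center"].to_numpy()
    hx = hotspots["x"].to_numpy()
    hmotif = hotspots["motif_center"].to_numpy()
    hctrl = hotspots["controlling_allele"].to_numpy()
    hid = hotspots["hotspot_id"].to_numpy()

    n_total = rng.poisson(config.dsb_per_meiosis_mean)
    n_co = rng.binomial(n_total, config.co_fraction)
    n_nco = n_total - n_co

    chroms = snp_map.chroms
    # --- crossover hotspot draw, resampled until each chromosome is hit
    p_heat = heats / heats.sum()
    if config.obligate_co:
        n_co = max(n_co, len(chroms))
        n_co = min(n_co, len(heats))
        for _ in range(1000):
            co_idx = rng.choice(len(heats), size=n_co, replace=False, p=p_heat)
            if set(chroms) <= set(hchrom[co_idx]):
                break
        else:  # pragma: no cover - pathological configs only
            missing = [c for c in chroms if c not in set(hchrom[co_idx])]
            extra = [
                rng.choice(np.where(hchrom == c)[0]) for c in missing
            ]
            co_idx = np.concatenate([co_idx, np.array(extra, dtype=int)])
    else:
        co_idx = rng.choice(
            len(heats), size=min(n_co, len(heats)), replace=False, p=p_heat
        )

    events: list[TrueEvent] = []
    gam_alleles, gam_ancestry = {}, {}
    cur_hap_by_chrom = {}

    for chrom in chroms:
        pos = snp_map.pos[chrom]
        hap_arrays = (parent.hap_mat, parent.hap_pat)
        start = int(rng.integers(0, 2))
        bks = np.sort(hcenter[co_idx][hchrom[co_idx] == chrom])
        # piecewise copy: segment s follows hap (start + s) % 2
        cut = np.searchsorted(pos, bks, side="right")
        cur = np.empty(len(pos), dtype=np.int8)
        bounds = np.concatenate([[0], cut, [len(pos)]])
        for s in range(len(bounds) - 1):
            cur[bounds[s] : bounds[s + 1]] = (start + s) % 2
        al = np.where(
            cur == 0, hap_arrays[0].alleles[chrom], hap_arrays[1].alleles[chrom]
        ).astype(np.int8)
        anc = np.where(
            cur == 0, hap_arrays[0].ancestry[chrom], hap_arrays[1].ancestry[chrom]
        ).astype(np.int8)
        gam_alleles[chrom] = al
        gam_ancestry[chrom] = anc
        cur_hap_by_chrom[chrom] = cur
        sub = co_idx[hchrom[co_idx] == chrom]
        order = np.argsort(hcenter[sub])
        for bk, ci in zip(hcenter[sub][order], sub[order]):
            i = np.searchsorted(pos, bk, side="right")
            rec = None
            if 0 < i <= len(pos):
                rec = "B6" if anc[min(i, len(pos)) - 1] == 0 else "CAST"
            events.append(
                TrueEvent(meiosis_id, "CO", chrom, int(hid[ci]), rec, breakpoint=int(bk))
            )

    # --- NCO draws: weight = heat * binding of the gamete's local ancestry
    bind = np.empty(len(heats))
    for chrom in chroms:
        m = hchrom == chrom
        pos = snp_map.pos[chrom]
        anc = gam_ancestry[chrom]
        if len(pos) == 0:
            bind[m] = 0.5
            continue
        nearest = np.clip(np.searchsorted(pos, hcenter[m]), 0, len(pos) - 1)
        local_anc = anc[nearest]
        bind[m] = np.where(local_anc == 0, hx[m], 1.0 - hx[m])
    w = heats * np.clip(bind, 1e-9, None)
    # a hotspot fires at most once per meiosis: no replacement, and CO
    # hotspots are not reused
    w[co_idx] = 0.0
    w = w / w.sum()
    n_nco = min(n_nco, int(np.sum(w > 0)))
    nco_idx = rng.choice(len(heats), size=n_nco, replace=False, p=w)

    for ci in nco_idx:
        chrom = hchrom[ci]
        pos = snp_map.pos[chrom]
        mean = (
            config.tract_mean_cast if hctrl[ci] == "Cast" else config.tract_mean_hum
        )
        L = max(1.0, rng.exponential(mean))
        c = hmotif[ci] + rng.normal(0.0, config.tract_center_sd)
        t0, t1 = c - L / 2.0, c + L / 2.0
        lo = np.searchsorted(pos, t0, side="left")
        hi = np.searchsorted(pos, t1, side="right")
        idx = np.arange(lo, hi)
        cur = cur_hap_by_chrom[chrom]
        if len(pos):
            near = int(np.clip(np.searchsorted(pos, hcenter[ci]), 0, len(pos) - 1))
            rec_label = "B6" if gam_ancestry[chrom][near] == 0 else "CAST"
            donor_hap = (parent.hap_mat, parent.hap_pat)[1 - cur[near]]
        else:
            rec_label = None
            donor_hap = parent.hap_pat
        informative = np.array([], dtype=np.int64)
        if len(idx):
            donor_alleles = donor_hap.alleles[chrom][idx]
            recipient_alleles = gam_alleles[chrom][idx]
            informative = idx[donor_alleles != recipient_alleles]
            gam_alleles[chrom][idx] = donor_alleles
        events.append(
            TrueEvent(
                meiosis_id,
                "NCO",
                chrom,
                int(hid[ci]),
                rec_label,
                tract_start=int(np.floor(t0)),
                tract_end=int(np.ceil(t1)),
                snp_indices=idx,
                informative=informative,
            )
        )

    return Haplotype(gam_alleles, gam_ancestry), events


# ---------------------------------------------------------------------------
# Pedigree


@dataclass
class Pedigree:
    """A simulated cross: individuals, truth events per meiosis, inputs."""

    individuals: dict
    events: dict  # meiosis_id -> list[TrueEvent]
    snp_map: SnpMap
    hotspots: pd.DataFrame
    config: SimConfig

    def samples(self, *generations) -> list:
        return [
            i.id
            for i in self.individuals.values()
            if not generations or i.generation in generations
        ]

    def meioses_into(self, *generations) -> list:
        """meiosis_ids whose child is in one of the given generations."""
        out = []
        for mid in self.events:
            child = mid.split(">")[1]
            if self.individuals[child].generation in generations:
                out.append(mid)
        return out


def _mate(
    ped: Pedigree,
    mother: Individual,
    father: Individual,
    child_id: str,
    generation: str,
    sex: str,
    config: SimConfig,
    rng,
):
    scale_f = config.sex_heat_multiplier
    gm, ev_m = simulate_meiosis(
        mother, ped.hotspots, ped.snp_map, config, rng,
        meiosis_id=f"{mother.id}>{child_id}", heat_scale=scale_f,
    )
    gp, ev_p = simulate_meiosis(
        father, ped.hotspots, ped.snp_map, config, rng,
        meiosis_id=f"{father.id}>{child_id}",
    )
    child = Individual(child_id, generation, sex, mother.id, father.id, gm, gp)
    ped.individuals[child_id] = child
    ped.events[f"{mother.id}>{child_id}"] = ev_m
    ped.events[f"{father.id}>{child_id}"] = ev_p
    return child


def simulate_pedigree(
    config: SimConfig,
    rng: np.random.Generator,
    n_f2: int = 11,
    n_lines: int = 18,
    f5_per_pair: int = 4,
    through: str = "F5",
    snp_map: Optional[SnpMap] = None,
    hotspots: Optional[pd.DataFrame] = None,
) -> Pedigree:
    """Simulate the cross design: F0 pair -> F1 pair -> 11 F2; 18 breeding
    lines each F2 pair -> F3 pair -> F4 pair -> 4 F5 offspring.

    ``through`` may be "F2" (stop after the sequenced F2s) or "F5".
    Truth events are retained per meiosis under ``pedigree.events``.
    """
    if snp_map is None:
        snp_map = simulate_snp_map(config, rng)
    if hotspots is None:
        hotspots = simulate_hotspots(config, snp_map, rng)
    f0_b6 = Individual(
        "F0_B6", "F0", "F", None, None,
        founder_haplotype(snp_map, 0), founder_haplotype(snp_map, 0),
    )
    f0_cast = Individual(
        "F0_CAST", "F0", "M", None, None,
        founder_haplotype(snp_map, 1), founder_haplotype(snp_map, 1),
    )
    ped = Pedigree({f0_b6.id: f0_b6, f0_cast.id: f0_cast}, {}, snp_map, hotspots, config)
    f1a = _mate(ped, f0_b6, f0_cast, "F1_0", "F1", "F", config, rng)
    f1b = _mate(ped, f0_b6, f0_cast, "F1_1", "F1", "M", config, rng)
    for i in range(n_f2):
        _mate(ped, f1a, f1b, f"F2_{i:02d}", "F2", "FM"[i % 2], config, rng)
    if through == "F2":
        return ped
    for line in range(n_lines):
        f2a = _mate(ped, f1a, f1b, f"F2B_{line:02d}a", "F2breeder", "F", config, rng)
        f2b = _mate(ped, f1a, f1b, f"F2B_{line:02d}b", "F2breeder", "M", config, rng)
        f3a = _mate(ped, f2a, f2b, f"F3_{line:02d}a", "F3", "F", config, rng)
        f3b = _mate(ped, f2a, f2b, f"F3_{line:02d}b", "F3", "M", config, rng)
        f4a = _mate(ped, f3a, f3b, f"F4_{line:02d}a", "F4", "F", config, rng)
        f4b = _mate(ped, f3a, f3b, f"F4_{line:02d}b", "F4", "M", config, rng)
        for j in range(f5_per_pair):
            _mate(
                ped, f4a, f4b, f"F5_{line:02d}_{j}", "F5", "FM"[j % 2], config, rng
            )
    return ped


# ---------------------------------------------------------------------------
# Genotype calls


@dataclass
class SampleGenotypes:
    """Per-sample genotype calls with total and allelic depths."""

    sample_id: str
    generation: str
    calls: dict  # chrom -> int8 array (0 homB6, 1 het, 2 homCAST, -1 missing)
    depth: dict  # chrom -> int32
    ad_b6: dict
    ad_cast: dict


_DEPTH_GEN = {"F0": "founder", "F4": "founder", "F1": "offspring",
              "F2": "offspring", "F2breeder": "offspring", "F3": "offspring",
              "F5": "offspring"}


def simulate_genotype_calls(
    pedigree: Pedigree,
    config: SimConfig,
    rng: np.random.Generator,
    sample_ids=None,
) -> dict:
    """Simulate depth-bearing genotype calls for the given samples.

    Depth is Poisson with the generation mean (10x founders/F4, 20x
    F2/F5); het allele reads are Binomial(depth, 1/2); hom sites acquire
    reads of the other allele at ``base_error_rate``.  Artifact modes
    (spurious unbalanced hets, spurious homs) are injected at
    ``false_het_rate`` / ``false_hom_rate``.  With
    ``config.exact_genotypes`` the depth is the mean exactly and het
    reads split evenly (noise-free mode).
    """
    if config.false_het_rate < 0 or config.false_hom_rate < 0:
        raise ValueError("artifact rates must be non-negative")
    if sample_ids is None:
        sample_ids = pedigree.samples("F0", "F2", "F4", "F5")
    out = {}
    for sid in sample_ids:
        ind = pedigree.individuals[sid]
        mean_depth = (
            config.depth_founder
            if _DEPTH_GEN.get(ind.generation, "offspring") == "founder"
            else config.depth_offspring
        )
        calls, depth, adb, adc = {}, {}, {}, {}
        for chrom in pedigree.snp_map.chroms:
            truth = ind.truth_genotypes(chrom)  # 0/1/2 CAST copies
            n = len(truth)
            if config.exact_genotypes:
                d = np.full(n, int(round(mean_depth)), dtype=np.int32)
                cast_reads = np.where(
                    truth == 1, d // 2, np.where(truth == 2, d, 0)
                ).astype(np.int32)
            else:
                d = rng.poisson(mean_depth, size=n).astype(np.int32)
                cast_reads = np.zeros(n, dtype=np.int32)
                het = truth == 1
                cast_reads[het] = rng.binomial(d[het], 0.5)
                hom_c = truth == 2
                hom_b = truth == 0
                if config.base_error_rate > 0:
                    err_b = rng.binomial(d[hom_b], config.base_error_rate)
                    err_c = rng.binomial(d[hom_c], config.base_error_rate)
                    cast_reads[hom_b] = err_b
                    cast_reads[hom_c] = d[hom_c] - err_c
                else:
                    cast_reads[hom_c] = d[hom_c]
            b6_reads = d - cast_reads
            call = np.full(n, MISSING, dtype=np.int8)
            called = d > 0
            both = (b6_reads > 0) & (cast_reads > 0)
            call[called & both] = HET
            call[called & ~both & (cast_reads == 0)] = HOM_B6
            call[called & ~both & (b6_reads == 0)] = HOM_CAST
            if not config.exact_genotypes:
                # artifact injection, to exercise the filter cascade
                if config.false_het_rate > 0:
                    hom_called = (call == HOM_B6) | (call == HOM_CAST)
                    inject = hom_called & (d >= 2) & (
                        rng.random(n) < config.false_het_rate
                    )
                    was_b6 = inject & (call == HOM_B6)
                    was_c = inject & (call == HOM_CAST)
                    minor = 1 + rng.binomial(1, 0.3, size=n)
                    minor = np.minimum(minor, d - 1)
                    cast_reads[was_b6] = minor[was_b6]
                    b6_reads[was_b6] = d[was_b6] - minor[was_b6]
                    b6_reads[was_c] = minor[was_c]
                    cast_reads[was_c] = d[was_c] - minor[was_c]
                    call[inject] = HET
                if config.false_hom_rate > 0:
                    inject = (call == HET) & (
                        rng.random(n) < config.false_hom_rate
                    )
                    to_b6 = inject & (b6_reads >= cast_reads)
                    to_c = inject & ~to_b6
                    b6_reads[to_b6] = d[to_b6]
                    cast_reads[to_b6] = 0
                    cast_reads[to_c] = d[to_c]
                    b6_reads[to_c] = 0
                    call[to_b6] = HOM_B6
                    call[to_c] = HOM_CAST
            calls[chrom] = call
            depth[chrom] = d
            adb[chrom] = b6_reads
            adc[chrom] = cast_reads
        out[sid] = SampleGenotypes(sid, ind.generation, calls, depth, adb, adc)
    return out


# ---------------------------------------------------------------------------
# ChIP count data


def simulate_chip_counts(
    hotspots: pd.DataFrame, config: SimConfig, rng: np.random.Generator
) -> pd.DataFrame:
    """Per-hotspot homologue-assignable DMC1 and H3K4me3 read counts.

    H3K4me3 totals are Poisson(alpha * heat) with the B6 count Binomial
    in the binding ratio x.  DMC1 totals are Poisson(beta * heat *
    delay(symmetry)) where delay interpolates from 1 at symmetric
    hotspots to ``dmc1_delay_factor`` (default 2) as symmetry goes to 0 —
    the repair-delay signature of asymmetric hotspots.  The DMC1 allele
    fraction is optionally shifted toward the less-bound homologue
    (``dmc1_shift``; 0 disables).
    """
    if config.chip_alpha <= 0 or config.chip_beta <= 0:
        raise ValueError("chip_alpha and chip_beta must be positive")
    h = hotspots["heat"].to_numpy()
    x = hotspots["x"].to_numpy()
    sym = 4.0 * x * (1.0 - x)
    n = len(hotspots)
    h3_total = rng.poisson(config.chip_alpha * h)
    h3_b6 = rng.binomial(h3_total, x)
    delay = 1.0 + (config.dmc1_delay_factor - 1.0) * (1.0 - sym)
    d_total = rng.poisson(config.chip_beta * h * delay)
    x_d = x - config.dmc1_shift * (1.0 - sym) * (2.0 * x - 1.0) / 2.0
    d_b6 = rng.binomial(d_total, np.clip(x_d, 0.0, 1.0))
    out = hotspots[["hotspot_id", "chrom", "center"]].copy()
    out["h3k4_total"] = h3_total
    out["h3k4_b6"] = h3_b6
    out["h3k4_cast"] = h3_total - h3_b6
    out["dmc1_total"] = d_total
    out["dmc1_b6"] = d_b6
    out["dmc1_cast"] = d_total - d_b6
    return out


# ---------------------------------------------------------------------------
# Stand-alone NCO events (tract-estimator checks)


@dataclass
class SimpleNco:
    """A bare NCO event: converted positions on a SNP map."""

    sample_id: str
    chrom: str
    positions: np.ndarray
    snp_indices: np.ndarray
    donor_is_cast: np.ndarray
    recipient: str = "B6"
    hotspot_id: Optional[int] = None
    complex: bool = False

    @property
    def n_converted(self) -> int:
        return len(self.positions)

    @property
    def min_tract(self):
        return (int(self.positions[0]), int(self.positions[-1]))

    @property
    def midpoint(self) -> float:
        return 0.5 * (self.positions[0] + self.positions[-1])


def simulate_isolated_ncos(
    n_events: int,
    tract_mean: float,
    rng: np.random.Generator,
    snp_spacing: float = 170.0,
    slot_bp: int = 50_000,
):
    """Draw NCO events with exponential tracts on a fresh SNP map.

    Events occupy well-separated slots of a single chromosome (one per
    ``slot_bp``), are redrawn until the tract contains at least one SNP
    (an empty tract is unobservable), and every SNP in the tract is
    converted.  Returns (snp_map, events) ready for
    :class:`~meiorec.tract.TractLengthModel`.
    """
    if n_events <= 0 or tract_mean <= 0:
        raise ValueError("n_events and tract_mean must be positive")
    length = (n_events + 1) * slot_bp
    cfg = SimConfig(chrom_lengths=(length,), snp_spacing_mean=snp_spacing)
    snp_map = simulate_snp_map(cfg, rng)
    chrom = snp_map.chroms[0]
    cpos = snp_map.pos[chrom]
    events = []
    for k in range(n_events):
        base = (k + 0.5) * slot_bp
        for _ in range(10_000):
            c = base + rng.uniform(-slot_bp / 4, slot_bp / 4)
            L = max(1.0, rng.exponential(tract_mean))
            lo = np.searchsorted(cpos, c - L / 2, "left")
            hi = np.searchsorted(cpos, c + L / 2, "right")
            if hi > lo:
                idx = np.arange(lo, hi)
                events.append(
                    SimpleNco(
                        sample_id=f"sim{k}",
                        chrom=chrom,
                        positions=cpos[idx].copy(),
                        snp_indices=idx,
                        donor_is_cast=np.ones(len(idx), dtype=bool),
                    )
                )
                break
        else:  # pragma: no cover
            raise RuntimeError("could not place a tract containing a SNP")
    return snp_map, events


# ---------------------------------------------------------------------------
# Truth export helpers


def events_to_frame(pedigree: Pedigree) -> pd.DataFrame:
    """Flatten the truth-event ledger to a DataFrame."""
    rows = []
    for mid, evs in pedigree.events.items():
        parent, child = mid.split(">")
        for e in evs:
            rows.append(
                {
                    "meiosis_id": mid,
                    "parent": parent,
                    "child": child,
                    "kind": e.kind,
                    "chrom": e.chrom,
                    "hotspot_id": e.hotspot_id,
                    "recipient": e.recipient,
                    "breakpoint": e.breakpoint,
                    "tract_start": e.tract_start,
                    "tract_end": e.tract_end,
                    "n_snps": 0 if e.snp_indices is None else len(e.snp_indices),
                    "n_informative": 0
                    if e.informative is None
                    else len(e.informative),
                }
            )
    return pd.DataFrame(rows)
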