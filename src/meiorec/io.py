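"""Readers and writers for the standard interchange formats.

Genotypes travel as VCF (GT/DP/AD; 1-based positions, REF = B6 allele,
ALT = CAST allele); events and hotspot peaks as BED6+ (0-based
half-open) with TSV sidecars; SNP maps, hotspot tables and truth
ledgers as TSV; configuration as YAML.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .simulate import SampleGenotypes, SnpMap

_GT = {0: "0/0", 1: "0/1", 2: "1/1", -1: "./."}


def write_vcf(path, snp_map: SnpMap, genotypes: dict, sample_order=None) -> None:
    """Write genotype calls with DP and AD for all samples to a VCF."""
    if sample_order is None:
        sample_order = list(genotypes)
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=meiorec\n")
        for chrom in snp_map.chroms:
            fh.write(
                f"##contig=<ID={chrom},length={snp_map.chrom_lengths[chrom]}>\n"
            )
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description="Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description="Depth">\n')
        fh.write(
            '##FORMAT=<ID=AD,Number=R,Type=Integer,Description="Allelic depths">\n'
        )
        fh.write(
            "#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
            + "\t".join(sample_order)
            + "\n"
        )
        for chrom in snp_map.chroms:
            pos = snp_map.pos[chrom]
            ref = snp_map.allele_b6[chrom]
            alt = snp_map.allele_cast[chrom]
            cols = []
            for sid in sample_order:
                g = genotypes[sid]
                cols.append(
                    (
                        g.calls[chrom],
                        g.depth[chrom],
                        g.ad_b6[chrom],
                        g.ad_cast[chrom],
                    )
                )
            for i in range(len(pos)):
                fields = [
                    chrom, str(pos[i]), ".", ref[i], alt[i], ".", "PASS",
                    ".", "GT:DP:AD",
                ]
                for calls, dp, adb, adc in cols:
                    fields.append(
                        f"{_GT[int(calls[i])]}:{dp[i]}:{adb[i]},{adc[i]}"
                    )
                fh.write("\t".join(fields) + "\n")


def read_vcf(path, generation_of=None):
    """Read a meiorec-style VCF back into (SnpMap, {sample: genotypes}).

    Uses cyvcf2.  ``generation_of`` maps sample id -> generation; by
    default the prefix before the first underscore is used (F0_B6 -> F0).
    """
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    samples = list(vcf.samples)
    chrom_lengths = dict(zip(vcf.seqnames, vcf.seqlens))
    pos_, ref_, alt_ = {}, {}, {}
    data = {s: {"call": {}, "dp": {}, "adb": {}, "adc": {}} for s in samples}
    cur = {c: [] for c in chrom_lengths}
    rows = []
    for v in vcf:
        gts = v.gt_types  # 0 hom-ref, 1 het, 2 unknown, 3 hom-alt
        call = np.where(
            gts == 0, 0, np.where(gts == 1, 1, np.where(gts == 3, 2, -1))
        )
        ad = v.format("AD")
        dp = v.format("DP").reshape(-1)
        rows.append((v.CHROM, v.POS, v.REF, v.ALT[0], call, dp, ad))
    bychrom: dict = {}
    for chrom, pos, ref, alt, call, dp, ad in rows:
        bychrom.setdefault(chrom, []).append((pos, ref, alt, call, dp, ad))
    snp_pos, snp_ref, snp_alt = {}, {}, {}
    out = {}
    chroms = [c for c in chrom_lengths if c in bychrom]
    for chrom in chroms:
        recs = bychrom[chrom]
        snp_pos[chrom] = np.array([r[0] for r in recs], dtype=np.int64)
        snp_ref[chrom] = np.array([r[1] for r in recs])
        snp_alt[chrom] = np.array([r[2] for r in recs])
    snp_map = SnpMap(
        {c: chrom_lengths[c] for c in chroms}, snp_pos, snp_ref, snp_alt
    )
    for si, sid in enumerate(samples):
        gen = (
            generation_of[sid]
            if generation_of is not None
            else sid.split("_")[0]
        )
        calls, depth, adb, adc = {}, {}, {}, {}
        for chrom in chroms:
            recs = bychrom[chrom]
            calls[chrom] = np.array([r[3][si] for r in recs], dtype=np.int8)
            depth[chrom] = np.array([r[4][si] for r in recs], dtype=np.int32)
            adb[chrom] = np.array([r[5][si][0] for r in recs], dtype=np.int32)
            adc[chrom] = np.array([r[5][si][1] for r in recs], dtype=np.int32)
        out[sid] = SampleGenotypes(sid, gen, calls, depth, adb, adc)
    return snp_map, out


def events_to_bed(events_table: pd.DataFrame, path) -> None:
    """Write called events as BED6+ (0-based half-open) with annotations."""
    df = events_table.copy()
    df["bed_start"] = df["start"].astype(int) - 1
    df["bed_end"] = df["end"].astype(int)
    df["name"] = df["sample_id"] + ":" + df["kind"]
    df["score"] = 0
    df["strand"] = "."
    cols = [
        "chrom", "bed_start", "bed_end", "name", "score", "strand",
        "kind", "sample_id", "positions", "recipient", "inheritance",
        "parent", "complex", "hotspot_id",
    ]
    df[cols].to_csv(path, sep="\t", index=False, header=False)


def peaks_to_bed(peaks: pd.DataFrame, path) -> None:
    df = peaks.copy()
    df["name"] = "hs" + df["hotspot_id"].astype(str)
    df["score"] = 0
    df["strand"] = "."
    df[["chrom", "start", "end", "name", "score", "strand"]].to_csv(
        path, sep="\t", index=False, header=False
    )
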