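"""Reading, validation and copy-number annotation of tumor inputs.

Segment files are tab-separated with header
``chrom start end cn b_allele coverage_ratio baf`` (missing values empty or
"NA"); mutation files are tab-separated ``chrom pos ref alt n_var n_ref`` or
a VCF with per-sample allelic depths.  Metadata (purity, ploidy, age,
sample type, telomere-maintenance status) comes from a YAML/JSON mapping.
"""

from __future__ import annotations

import json
import logging
from typing import Optional

import numpy as np
import pandas as pd
from scipy import stats

from .datatypes import CnaEventReport, MutationCall, SegmentProfile, TumorSample

logger = logging.getLogger(__name__)

# hg19 chromosome lengths and centromere midpoints (bp); the minimal arm
# table needed to annotate arm-level events.
HG19_ARMS = {
    "1": (249_250_621, 125_000_000),
    "2": (243_199_373, 93_300_000),
    "3": (198_022_430, 91_000_000),
    "4": (191_154_276, 50_400_000),
    "5": (180_915_260, 48_400_000),
    "6": (171_115_067, 61_000_000),
    "7": (159_138_663, 59_900_000),
    "8": (146_364_022, 45_600_000),
    "9": (141_213_431, 49_000_000),
    "10": (135_534_747, 40_200_000),
    "11": (135_006_516, 53_700_000),
    "12": (133_851_895, 35_800_000),
    "13": (115_169_878, 17_900_000),
    "14": (107_349_540, 17_600_000),
    "15": (102_531_392, 19_000_000),
    "16": (90_354_753, 36_600_000),
    "17": (81_195_210, 24_000_000),
    "18": (78_077_248, 17_200_000),
    "19": (59_128_983, 26_500_000),
    "20": (63_025_520, 27_500_000),
    "21": (48_129_895, 13_200_000),
    "22": (51_304_566, 14_700_000),
}

MAX_TIMEABLE_CN = 4
MIN_TIMEABLE_BP = 10_000_000  # segments of size <= 1e7 bp are excluded


def _norm_chrom(c) -> str:
    c = str(c)
    return c[3:] if c.lower().startswith("chr") else c


# ----------------------------------------------------------------------
# ingestion
# ----------------------------------------------------------------------

def read_segments(path, one_based: bool = False) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str}, na_values=["NA", ""])
    required = {"chrom", "start", "end"}
    if not required.issubset(df.columns):
        raise ValueError(f"segment file must contain columns {sorted(required)}")
    segs = []
    for row in df.itertuples(index=False):
        start = int(row.start) - 1 if one_based else int(row.start)
        end = int(row.end) if one_based else int(row.end)

        def _opt(name, cast):
            v = getattr(row, name, None)
            if v is None or (isinstance(v, float) and np.isnan(v)):
                return None
            return cast(v)

        segs.append(
            SegmentProfile(
                chrom=_norm_chrom(row.chrom),
                start=start,
                end=end,
                cn=_opt("cn", int),
                b_allele=_opt("b_allele", int),
                coverage_ratio=_opt("coverage_ratio", float),
                baf=_opt("baf", float),
            )
        )
    return segs


def read_mutations_tsv(path, one_based: bool = False) -> list:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    muts = []
    for row in df.itertuples(index=False):
        pos = int(row.pos) - 1 if one_based else int(row.pos)
        muts.append(
            MutationCall(
                chrom=_norm_chrom(row.chrom),
                pos=pos,
                ref=str(getattr(row, "ref", "N")),
                alt=str(getattr(row, "alt", "N")),
                n_var=int(row.n_var),
                n_ref=int(row.n_ref),
            )
        )
    return muts


def read_mutations_vcf(path, sample: Optional[str] = None) -> list:
    """Read SNVs with AD-style allelic depths from a VCF (requires cyvcf2)."""
    from cyvcf2 import VCF  # lazy: only needed for VCF input

    vcf = VCF(path)
    idx = 0
    if sample is not None:
        idx = vcf.samples.index(sample)
    muts = []
    for rec in vcf:
        if rec.gt_alt_depths is None:
            continue
        n_var = int(rec.gt_alt_depths[idx])
        n_ref = int(rec.gt_ref_depths[idx])
        if n_var < 1:
            continue
        muts.append(
            MutationCall(
                chrom=_norm_chrom(rec.CHROM),
                pos=rec.POS - 1,
                ref=rec.REF,
                alt=rec.ALT[0] if rec.ALT else "N",
                n_var=n_var,
                n_ref=n_ref,
            )
        )
    return muts


def assign_mutations_to_segments(segments, mutations) -> int:
    """Link each mutation to its containing segment (half-open intervals).

    Overlapping segments on the same chromosome raise; mutations outside all
    segments keep ``segment_id=None`` and are excluded downstream.  Returns
    the number of unassigned mutations.
    """
    by_chrom: dict = {}
    for i, seg in enumerate(segments):
        by_chrom.setdefault(seg.chrom, []).append((seg.start, seg.end, i))
    for chrom, ivs in by_chrom.items():
        ivs.sort()
        for (s1, e1, _), (s2, _e2, _) in zip(ivs, ivs[1:]):
            if s2 < e1:
                raise ValueError(f"overlapping segments on chromosome {chrom}")
    unassigned = 0
    for mut in mutations:
        mut.segment_id = None
        for s, e, i in by_chrom.get(mut.chrom, ()):
            if s <= mut.pos < e:
                mut.segment_id = i
                break
        if mut.segment_id is None:
            unassigned += 1
    if unassigned:
        logger.info("%d mutations outside all segments (dropped downstream)", unassigned)
    return unassigned


def read_tumor(
    segments_path,
    mutations_path,
    meta,
    one_based: bool = False,
    vcf_sample: Optional[str] = None,
) -> TumorSample:
    """Assemble a validated :class:`TumorSample` from files plus metadata.

    ``meta`` is a mapping (or path to YAML/JSON) with at least ``sample_id``,
    ``purity`` and ``ploidy``.
    """
    if not isinstance(meta, dict):
        meta = _load_meta(meta)
    segments = read_segments(segments_path, one_based=one_based)
    mpath = str(mutations_path)
    if mpath.endswith((".vcf", ".vcf.gz")):
        mutations = read_mutations_vcf(mutations_path, sample=vcf_sample)
    else:
        mutations = read_mutations_tsv(mutations_path, one_based=one_based)
    assign_mutations_to_segments(segments, mutations)
    return TumorSample(
        sample_id=str(meta["sample_id"]),
        purity=float(meta["purity"]),
        ploidy=float(meta["ploidy"]),
        age_days=meta.get("age_days"),
        sample_type=meta.get("sample_type", "primary"),
        tmm=meta.get("tmm", "unknown"),
        segments=segments,
        mutations=mutations,
    )


def write_segments(segments, path) -> None:
    """SEG-compatible tab-separated export (0-based half-open)."""
    with open(path, "w") as fh:
        fh.write("chrom\tstart\tend\tcn\tb_allele\tcoverage_ratio\tbaf\n")
        for s in segments:
            fields = [s.chrom, s.start, s.end, s.cn, s.b_allele,
                      s.coverage_ratio, s.baf]
            fh.write("\t".join("" if v is None else str(v) for v in fields) + "\n")


def write_mutations(mutations, path) -> None:
    with open(path, "w") as fh:
        fh.write("chrom\tpos\tref\talt\tn_var\tn_ref\n")
        for m in mutations:
            fh.write(f"{m.chrom}\t{m.pos}\t{m.ref}\t{m.alt}\t{m.n_var}\t{m.n_ref}\n")


def _load_meta(path) -> dict:
    import yaml

    with open(path) as fh:
        if str(path).endswith(".json"):
            return json.load(fh)
        return yaml.safe_load(fh)


# ----------------------------------------------------------------------
# copy-number state assignment and selection
# ----------------------------------------------------------------------

def expected_coverage_ratio(cn: int, purity: float, ploidy: float) -> float:
    """Expected tumor/control coverage ratio of a CN state in an impure sample."""
    return (cn * purity + 2 * (1 - purity)) / (ploidy * purity + 2 * (1 - purity))


def assign_missing_cn(
    segment: SegmentProfile,
    purity: float,
    ploidy: float,
    cr_tol: float = 0.1,
    baf_tol: float = 0.05,
    max_cn: int = 8,
):
    """Assign an integer CN state from measured coverage ratio and BAF.

    A state (CN, b) matches when the expected coverage ratio lies within
    ``cr_tol`` of the measured CR and b/CN lies within ``baf_tol`` of the
    measured BAF.  Returns ``(cn, b)`` for a unique match, ``None`` if no
    state — or more than one — matches (ambiguity is treated conservatively).
    """
    if purity is None or ploidy is None:
        raise ValueError("purity and ploidy are required to assign CN states")
    if segment.coverage_ratio is None or segment.baf is None:
        return None
    matches = []
    for cn in range(1, max_cn + 1):
        if abs(expected_coverage_ratio(cn, purity, ploidy) - segment.coverage_ratio) > cr_tol:
            continue
        for b in range(0, cn + 1):
            if abs(b / cn - segment.baf) <= baf_tol:
                matches.append((cn, b))
    if len(matches) == 1:
        return matches[0]
    return None


def resolve_cn_states(sample: TumorSample, **kwargs) -> int:
    """Fill in missing CN states via CR/BAF matching; returns #still-missing."""
    missing = 0
    for seg in sample.segments:
        if seg.cn is None:
            state = assign_missing_cn(seg, sample.purity, sample.ploidy, **kwargs)
            if state is None:
                missing += 1
            else:
                seg.cn, seg.b_allele = state
    if missing:
        logger.info("%d segments lack a CN call and a CR/BAF match; dropped", missing)
    return missing


def select_timeable_segments(sample: TumorSample) -> list:
    """Autosomal segments usable for the molecular clock.

    Keeps segments with an assigned CN state, CN <= 4 and size strictly
    greater than 1e7 bp (short pieces and high CN states give ambiguous
    mutation statistics).
    """
    kept = []
    for i, seg in enumerate(sample.segments):
        if seg.cn is None or seg.b_allele is None:
            continue
        if not seg.is_autosomal:
            continue
        if seg.cn > MAX_TIMEABLE_CN or seg.size_bp <= MIN_TIMEABLE_BP or seg.cn == 0:
            continue
        kept.append((i, seg))
    return kept


def merge_segment_classes(sample: TumorSample, merge_by: str = "cn_b") -> list:
    """Group timeable segments into genomic classes of equal (CN, b).

    ``merge_by="cn_b"`` pools all segments of one allelic state genome-wide
    into a single genomic class (the default unit for timing);
    ``merge_by="chrom"`` keeps chromosomes separate.  Returns a list of dicts
    with keys ``cn, b, size_bp, segment_ids, mutations``.
    """
    groups: dict = {}
    for i, seg in select_timeable_segments(sample):
        key = (seg.cn, seg.b_allele) if merge_by == "cn_b" else (seg.chrom, seg.cn, seg.b_allele)
        g = groups.setdefault(key, {"cn": seg.cn, "b": seg.b_allele, "size_bp": 0,
                                    "segment_ids": [], "chroms": set()})
        g["size_bp"] += seg.size_bp
        g["segment_ids"].append(i)
        g["chroms"].add(seg.chrom)
    id2group = {}
    for g in groups.values():
        g["mutations"] = []
        g["chroms"] = sorted(g["chroms"])
        for i in g["segment_ids"]:
            id2group[i] = g
    for mut in sample.mutations:
        if mut.segment_id in id2group and mut.chrom not in ("X", "Y"):
            id2group[mut.segment_id]["mutations"].append(mut)
    return list(groups.values())


# ----------------------------------------------------------------------
# ploidy class and event annotation
# ----------------------------------------------------------------------

def classify_ploidy_class(ploidy: float) -> int:
    """Nearest of {2, 3, 4} to the average ploidy; ties round up."""
    if ploidy <= 0:
        raise ValueError("ploidy must be positive")
    if ploidy < 2.5:
        return 2
    if ploidy < 3.5:
        return 3
    return 4


def _arm_cn(segments, chrom: str, arm: str):
    """Length-weighted mean CN of the p or q arm; None if uncovered."""
    if chrom not in HG19_ARMS:
        raise ValueError(
            f"no arm annotation for chromosome {chrom}: the built-in hg19 arm "
            "table covers autosomes 1-22"
        )
    length, cen = HG19_ARMS[chrom]
    lo, hi = (0, cen) if arm == "p" else (cen, length)
    tot, wsum = 0, 0.0
    for seg in segments:
        if seg.chrom != chrom or seg.cn is None:
            continue
        ov = min(seg.end, hi) - max(seg.start, lo)
        if ov > 0:
            tot += ov
            wsum += ov * seg.cn
    return (wsum / tot) if tot > 0 else None


def annotate_cna_events(sample: TumorSample) -> CnaEventReport:
    """Annotate characteristic neuroblastoma copy-number events.

    Focal amplification: any region with CN >= 10.  Homozygous deletion:
    CN < 0.9.  1p (11q) loss: the arm is lost relative to 1q (11p) and its CN
    is <= 1 / <= 2 / <= 3 in near-di-/tri-/tetraploid tumors.  Whole gains of
    chromosomes 1, 2, 7 and 17 require CN above the rounded basal ploidy on
    both arms; partial gains of 1q, 2p, 7q and 17q require the arm to be
    gained relative to its sister arm.
    """
    pc = classify_ploidy_class(sample.ploidy)
    rep = CnaEventReport(ploidy_class=pc)
    segs = [s for s in sample.segments if s.cn is not None]
    rep.focal_amplification = any(s.cn >= 10 for s in segs)
    rep.homozygous_deletion = any(s.cn < 0.9 for s in segs)

    loss_cut = {2: 1, 3: 2, 4: 3}[pc]
    for chrom, attr in (("1", "loss_1p"), ("11", "loss_11q")):
        lost_arm = "p" if chrom == "1" else "q"
        other_arm = "q" if lost_arm == "p" else "p"
        cn_lost = _arm_cn(segs, chrom, lost_arm)
        cn_other = _arm_cn(segs, chrom, other_arm)
        if cn_lost is not None and cn_other is not None:
            setattr(rep, attr, cn_lost < cn_other and round(cn_lost) <= loss_cut)

    for chrom in ("1", "2", "7", "17"):
        cn_p = _arm_cn(segs, chrom, "p")
        cn_q = _arm_cn(segs, chrom, "q")
        if cn_p is None or cn_q is None:
            rep.whole_gain[chrom] = False
        else:
            rep.whole_gain[chrom] = round(cn_p) > pc and round(cn_q) > pc
    for arm in ("1q", "2p", "7q", "17q"):
        chrom, a = arm[:-1], arm[-1]
        sister = "q" if a == "p" else "p"
        cn_a = _arm_cn(segs, chrom, a)
        cn_s = _arm_cn(segs, chrom, sister)
        rep.partial_gain[arm] = (
            cn_a is not None and cn_s is not None and cn_a > cn_s
        )
    return rep


# ----------------------------------------------------------------------
# clonal / subclonal classification
# ----------------------------------------------------------------------

def classify_subclonal_binomial(
    mutation: MutationCall, cn: int, purity: float, alpha: float = 0.05
) -> str:
    """Binomial test for subclonality of a single SSNV.

    A mutation is subclonal when the binomial CDF of its variant read count,
    with success probability p = rho / (rho*CN + 2(1-rho)) (a single-copy
    clonal mutation) at its observed depth, falls below ``alpha``.
    """
    depth = mutation.n_var + mutation.n_ref
    if depth == 0:
        raise ValueError("zero-depth mutation")
    p = purity / (purity * cn + 2.0 * (1.0 - purity))
    cdf = stats.binom.cdf(mutation.n_var, depth, p)
    return "subclonal" if cdf < alpha else "clonal"
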