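"""Readers and writers for site tables, recombination maps and VCF input.

On-disk conventions: site tables and VCF positions are 1-based; emitted
intervals (BED) are 0-based half-open.  All readers reject malformed input
rather than silently coercing it, and every dropped record increments a named
counter so that conversions are auditable.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import SiteSequence

logger = logging.getLogger("elscan")

SITE_TABLE_COLUMNS = ["chrom", "pos", "derived_count", "total_chroms", "archaic_allele"]


class SiteTableError(ValueError):
    """Raised for malformed site tables."""


class MapError(ValueError):
    """Raised for malformed recombination maps."""


@dataclass
class RecombinationMap:
    """Piecewise-linear map from physical position (bp) to cumulative cM.

    Queries between knots are linearly interpolated; queries beyond the covered
    range are clamped to the terminal cumulative values (with a counted
    warning), i.e. the map extrapolates with rate zero.
    """

    pos: np.ndarray
    cum_cm: np.ndarray
    name: str = "map"
    chrom: str | None = None
    n_clamped: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        self.pos = np.asarray(self.pos, dtype=float)
        self.cum_cm = np.asarray(self.cum_cm, dtype=float)
        if len(self.pos) < 2:
            raise MapError("a recombination map needs at least two knots")
        if np.any(np.diff(self.pos) <= 0):
            raise MapError("map positions must be strictly increasing")
        if np.any(np.diff(self.cum_cm) < 0):
            raise MapError("cumulative cM must be nondecreasing")

    @classmethod
    def uniform(cls, rate_cm_per_mb: float, length_bp: float, name: str = "uniform"):
        """Constant-rate map covering ``[0, length_bp]``."""
        return cls(
            pos=np.array([0.0, float(length_bp)]),
            cum_cm=np.array([0.0, rate_cm_per_mb * length_bp / 1e6]),
            name=name,
        )

    def covers(self, start: float, end: float) -> bool:
        return start >= self.pos[0] and end <= self.pos[-1]

    def gpos(self, pos) -> np.ndarray:
        """Cumulative genetic position (cM) at physical position(s)."""
        pos = np.asarray(pos, dtype=float)
        out_of_range = int(np.sum((pos < self.pos[0]) | (pos > self.pos[-1])))
        if out_of_range:
            self.n_clamped += out_of_range
            logger.warning(
                "%d position(s) outside map %s coverage; clamped to terminal cM",
                out_of_range, self.name,
            )
        return np.interp(pos, self.pos, self.cum_cm)

    def distance(self, start: float, end: float) -> float:
        """Genetic length in cM of the physical interval [start, end]."""
        a, b = self.gpos(np.array([start, end]))
        return float(b - a)


def read_recomb_map(path, dialect: str = "cumulative", name: str | None = None) -> RecombinationMap:
    """Read a two-column recombination map.

    ``dialect="cumulative"`` expects columns (pos, cumulative cM);
    ``dialect="rate"`` expects (pos, rate in cM/Mb), integrated to cumulative
    cM with the rate of each row applying up to the next row's position.
    """
    df = pd.read_csv(path, sep=r"\s+", comment="#")
    if df.shape[1] < 2:
        raise MapError(f"{path}: expected at least two columns")
    pos = df.iloc[:, 0].to_numpy(dtype=float)
    val = df.iloc[:, 1].to_numpy(dtype=float)
    if name is None:
        name = str(path)
    if dialect == "cumulative":
        return RecombinationMap(pos=pos, cum_cm=val, name=name)
    if dialect == "rate":
        if np.any(val < 0):
            raise MapError(f"{path}: negative recombination rate")
        cum = np.concatenate([[0.0], np.cumsum(val[:-1] * np.diff(pos) / 1e6)])
        return RecombinationMap(pos=pos, cum_cm=cum, name=name)
    raise MapError(f"unknown recombination-map dialect {dialect!r}")


def write_site_table(seq: SiteSequence, path) -> None:
    """Write a site sequence as a TSV site table (1-based positions)."""
    data = {
        "chrom": [seq.chrom] * len(seq),
        "pos": seq.pos,
        "derived_count": seq.derived_count,
        "total_chroms": [seq.n_chrom] * len(seq),
        "archaic_allele": np.where(seq.archaic_derived, "D", "A"),
    }
    df = pd.DataFrame(data)
    for mname, g in seq.gpos.items():
        df[f"gpos_{mname}"] = np.round(g, 10)
    df.to_csv(path, sep="\t", index=False)


def read_site_table(path) -> SiteSequence:
    """Read a TSV site table back into a :class:`SiteSequence`.

    The table must be sorted by position, free of duplicate positions, with
    archaic alleles coded ``A`` (ancestral) or ``D`` (derived) and
    ``derived_count`` in ``[1, total_chroms]``.
    """
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    missing = [c for c in SITE_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise SiteTableError(f"{path}: missing column(s) {missing}")
    if df["chrom"].nunique() > 1:
        raise SiteTableError(f"{path}: a site table holds one chromosome per file")
    pos = df["pos"].to_numpy()
    bad = np.flatnonzero(np.diff(pos) <= 0)
    if bad.size:
        line = bad[0] + 3  # header + 1-based + offending second row
        raise SiteTableError(f"{path}: positions not strictly increasing at line {line}")
    alleles = df["archaic_allele"].astype(str)
    bad_allele = ~alleles.isin(["A", "D"])
    if bad_allele.any():
        line = int(np.flatnonzero(bad_allele.to_numpy())[0]) + 2
        raise SiteTableError(
            f"{path}: invalid archaic allele {alleles[bad_allele].iloc[0]!r} at line {line}"
        )
    n = df["total_chroms"].to_numpy()
    if len(np.unique(n)) != 1:
        raise SiteTableError(f"{path}: total_chroms must be constant")
    dc = df["derived_count"].to_numpy()
    if np.any(dc < 1) or np.any(dc > n[0]):
        line = int(np.flatnonzero((dc < 1) | (dc > n[0]))[0]) + 2
        raise SiteTableError(f"{path}: derived_count outside [1, total_chroms] at line {line}")
    gpos = {
        c[len("gpos_"):]: df[c].to_numpy(dtype=float)
        for c in df.columns
        if c.startswith("gpos_")
    }
    chrom = str(df["chrom"].iloc[0])
    return SiteSequence(
        pos=pos,
        derived_count=dc,
        archaic_derived=(alleles == "D").to_numpy(),
        n_chrom=int(n[0]),
        gpos=gpos,
        chrom=chrom,
        chrom_is_X=chrom.upper() in ("X", "CHRX"),
    )


def annotate_gpos(seq: SiteSequence, rec_map: RecombinationMap) -> SiteSequence:
    """Attach cumulative genetic positions under ``rec_map`` to a sequence."""
    seq.gpos[rec_map.name] = rec_map.gpos(seq.pos)
    return seq


def sites_from_vcf(
    vcf_path,
    panel_samples: list[str],
    archaic_samples: list[str],
    chrom: str | None = None,
    ancestral_tag: str = "AA",
    het_policy: str = "derived-if-any",
    seed: int = 0,
    mask=None,
) -> tuple[SiteSequence, Counter]:
    """Extract informative sites from a VCF carrying the panel and archaic samples.

    Sites are polarized using the ancestral allele in INFO field
    ``ancestral_tag``.  Only biallelic SNPs where the ancestral allele matches
    REF or ALT are kept; sites where the archaic carries a third allele are
    dropped (the VCF shows them as multiallelic), as are sites that are neither
    polymorphic nor fixed derived in the panel.  Heterozygous archaic genotypes
    are resolved by ``het_policy``: ``derived-if-any`` (default),
    ``ancestral-if-any`` or ``random`` (seeded).

    Returns the site sequence (without genetic positions; see
    :func:`annotate_gpos`) and a counter of dropped-record reasons.
    """
    from cyvcf2 import VCF

    if het_policy not in ("derived-if-any", "ancestral-if-any", "random"):
        raise ValueError(f"unknown archaic heterozygote policy {het_policy!r}")
    rng = np.random.default_rng(seed)
    vcf = VCF(str(vcf_path))
    samples = vcf.samples
    panel_idx = [samples.index(s) for s in panel_samples]
    arc_idx = [samples.index(s) for s in archaic_samples]
    counters: Counter = Counter()
    pos_l, dc_l, arc_l = [], [], []
    seen_chrom = None
    n_chrom = None
    for rec in vcf:
        if chrom is not None and rec.CHROM != chrom:
            continue
        if seen_chrom is None:
            seen_chrom = rec.CHROM
        elif rec.CHROM != seen_chrom:
            raise SiteTableError("VCF spans several chromosomes; pass chrom= to select one")
        if not rec.is_snp or len(rec.ALT) != 1:
            counters["not_biallelic_snp"] += 1
            continue
        aa = rec.INFO.get(ancestral_tag)
        if aa is None:
            counters["missing_ancestral"] += 1
            continue
        aa = str(aa).upper()
        if aa == rec.REF:
            derived = rec.ALT[0]
        elif aa == rec.ALT[0]:
            derived = rec.REF
        else:
            counters["unpolarizable"] += 1
            continue
        gts = rec.genotype.array()[:, :-1]  # drop phasing column
        panel_gt = gts[panel_idx].ravel()
        panel_gt = panel_gt[panel_gt >= 0]
        if n_chrom is None:
            n_chrom = panel_gt.size
        if panel_gt.size != n_chrom:
            counters["panel_missing_genotype"] += 1
            continue
        derived_is_alt = derived == rec.ALT[0]
        dcount = int((panel_gt == 1).sum() if derived_is_alt else (panel_gt == 0).sum())
        if dcount == 0:
            counters["not_informative"] += 1
            continue
        arc_gt = gts[arc_idx].ravel()
        arc_gt = arc_gt[arc_gt >= 0]
        if arc_gt.size == 0:
            counters["archaic_missing_genotype"] += 1
            continue
        arc_derived_alleles = (arc_gt == 1) if derived_is_alt else (arc_gt == 0)
        if arc_derived_alleles.all():
            arc_derived = True
        elif not arc_derived_alleles.any():
            arc_derived = False
        elif het_policy == "derived-if-any":
            arc_derived = True
        elif het_policy == "ancestral-if-any":
            arc_derived = False
        else:
            arc_derived = bool(rng.random() < arc_derived_alleles.mean())
        if mask is not None and any(s <= rec.POS - 1 < e for s, e in mask):
            counters["masked"] += 1
            continue
        pos_l.append(rec.POS)
        dc_l.append(dcount)
        arc_l.append(arc_derived)
    if n_chrom is None:
        raise SiteTableError("no usable records in VCF")
    counters["kept"] = len(pos_l)
    seq = SiteSequence(
        pos=np.array(pos_l, dtype=np.int64),
        derived_count=np.array(dc_l, dtype=np.int64),
        archaic_derived=np.array(arc_l, dtype=bool),
        n_chrom=n_chrom,
        gpos={},
        chrom=seen_chrom or (chrom or "1"),
        chrom_is_X=(seen_chrom or "").upper() in ("X", "CHRX"),
    )
    return seq, counters
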