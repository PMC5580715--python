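"""Simulation harness: exact-model sequences and coalescent scenarios.

Two families of generators are provided.

* :func:`simulate_from_hmm` draws sequences from the lineage-sorting HMM
  itself (known parameters, known state path) — the exact-model oracle used to
  validate parameter inference.

* :func:`simulate_neutral`, :func:`simulate_sweep`,
  :func:`simulate_neutral_fixation` and
  :func:`simulate_background_selection_proxy` build coalescent (msprime) or
  forward-in-time scenarios of a human panel, one or more archaic lineages and
  their ancestral population, and return informative-site tables together with
  the true per-site genealogy labels (archaic internal/external) read off the
  marginal trees.

Default demography: 370 modern human chromosomes from a single African
population (Ne 14,474 in the last 175 ky, 29,000 before, following
sequentially-Markovian-coalescent profiles of African history), an archaic
population (Ne 2,500) splitting 650 kya and sampled 120 kya, ancestral Ne
18,500; mutation rate 1.45e-8 per bp per generation, uniform recombination
1 cM/Mb, generation time 29 yr.  Selection coefficients are heterozygote
advantages (fitnesses 1, 1+s, 1+2s).
Simulations emit the true ancestral state directly; an optional
polarization-error rate can flip it for robustness experiments.  Substitutions
on the stem shared by humans and archaics (between the outgroup divergence and
the local grand MRCA) are overlaid analytically as fixed-derived sites carrying
the derived archaic allele, so site tables have the same composition as data
polarized against a deep outgroup.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import msprime
import numpy as np
import tskit

from .model import ModelParams, SiteSequence, transition_matrix

MAP_NAME = "uniform"  # name of the constant-rate map attached to simulated sequences


@dataclass
class DemographyConfig:
    """Split demography relating the human panel to the archaic lineage."""

    n_modern: int = 370
    n_archaic: int = 1
    n_outgroup: int = 0
    ne_modern: float = 14_474.0
    ne_modern_deep: float = 29_000.0
    t_deep_kya: float = 175.0
    ne_archaic: float = 2_500.0
    ne_ancestral: float = 18_500.0
    ne_outgroup: float = 20_000.0
    t_split_kya: float = 650.0
    t_archaic_sample_kya: float = 120.0
    t_outgroup_split_kya: float = 6_000.0
    mutation_rate: float = 1.45e-8
    recomb_cm_per_mb: float = 1.0
    generation_years: float = 29.0
    polarization_error: float = 0.0
    #: include fixed-derived positions where the archaic also carries the
    #: derived allele (substitutions predating the split).  Real scans use
    #: catalogs of human-specific changes, ascertained to be ancestral in the
    #: archaics, so these shared substitutions are excluded by default.
    include_shared_fixed: bool = True

    def __post_init__(self) -> None:
        for name in ("ne_modern", "ne_archaic", "ne_ancestral", "mutation_rate",
                     "recomb_cm_per_mb", "generation_years"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")
        if not self.t_archaic_sample_kya < self.t_split_kya < self.t_outgroup_split_kya:
            raise ValueError("times must satisfy archaic sample < split < outgroup split")
        if self.n_modern < 2 or self.n_archaic < 1:
            raise ValueError("need at least 2 modern and 1 archaic chromosome")

    @property
    def recomb_per_bp(self) -> float:
        return self.recomb_cm_per_mb * 1e-8

    def gens(self, kya: float) -> float:
        return kya * 1000.0 / self.generation_years

    @property
    def t_split_gens(self) -> float:
        return self.gens(self.t_split_kya)

    @property
    def t_deep_gens(self) -> float:
        return self.gens(self.t_deep_kya)

    def to_demography(self) -> msprime.Demography:
        d = msprime.Demography()
        d.add_population(name="AFR", initial_size=self.ne_modern)
        d.add_population(name="ARC", initial_size=self.ne_archaic)
        d.add_population(name="ANC", initial_size=self.ne_ancestral)
        if self.ne_modern_deep != self.ne_modern:
            d.add_population_parameters_change(
                time=self.t_deep_gens, population="AFR",
                initial_size=self.ne_modern_deep,
            )
        derived = ["AFR", "ARC"]
        if self.n_outgroup > 0:
            d.add_population(name="OUT", initial_size=self.ne_outgroup)
            d.add_population(name="ROOT", initial_size=self.ne_ancestral)
            d.add_population_split(time=self.t_split_gens, derived=derived, ancestral="ANC")
            d.add_population_split(
                time=self.gens(self.t_outgroup_split_kya),
                derived=["ANC", "OUT"], ancestral="ROOT",
            )
        else:
            d.add_population_split(time=self.t_split_gens, derived=derived, ancestral="ANC")
        return d

    def sample_sets(self) -> list[msprime.SampleSet]:
        sets = [
            msprime.SampleSet(self.n_modern, population="AFR", ploidy=1),
            msprime.SampleSet(
                self.n_archaic, population="ARC",
                time=self.gens(self.t_archaic_sample_kya), ploidy=1,
            ),
        ]
        if self.n_outgroup > 0:
            sets.append(msprime.SampleSet(self.n_outgroup, population="OUT", ploidy=1))
        return sets


@dataclass
class SweepConfig:
    """A positively selected mutation on the modern-human branch."""

    s: float = 0.005
    age_kya: float = 500.0
    position: float | None = None  # default: region midpoint
    conditioning: str = "fixed"  # {"fixed", "any"}

    def __post_init__(self) -> None:
        if self.s < 0:
            raise ValueError("selection coefficient must be >= 0")
        if self.age_kya <= 0:
            raise ValueError("mutation age must be > 0")
        if self.conditioning not in ("fixed", "any"):
            raise ValueError(f"unknown conditioning {self.conditioning!r}")


@dataclass
class SimulatedRegion:
    """A simulated region with informative sites and true genealogy labels.

    ``external`` flags, per informative site, whether the (first) archaic
    lineage is an outgroup to all sampled modern lineages in the marginal tree
    at that position; ``tracts`` are the maximal external intervals in bp
    (0-based half-open).
    """

    seq: SiteSequence
    external: np.ndarray
    tracts: list[tuple[float, float]]
    region_bp: int
    demog: DemographyConfig
    selected_pos: int | None = None
    fixed: bool | None = None
    s: float = 0.0
    age_kya: float | None = None
    seed: int = 0
    ts: tskit.TreeSequence | None = field(default=None, repr=False)

    @property
    def external_fraction(self) -> float:
        return sum(r - l for l, r in self.tracts) / self.region_bp

    def external_lengths_cm(self) -> np.ndarray:
        """Genetic lengths (cM) of all external tracts (uniform map)."""
        rate = self.demog.recomb_cm_per_mb * 1e-6
        return np.array([(r - l) * rate for l, r in self.tracts])

    def focal_tract_cm(self) -> float | None:
        """Genetic length of the external tract containing the selected site."""
        if self.selected_pos is None:
            return None
        for l, r in self.tracts:
            if l <= self.selected_pos < r:
                return (r - l) * self.demog.recomb_cm_per_mb * 1e-6
        return None

    def true_els_site_mask(self) -> np.ndarray:
        """Sites inside the external tract containing the selected variant."""
        mask = np.zeros(len(self.seq), dtype=bool)
        if self.selected_pos is None:
            return mask
        for l, r in self.tracts:
            if l <= self.selected_pos < r:
                mask |= (self.seq.pos - 1 >= l) & (self.seq.pos - 1 < r)
        return mask


# ---------------------------------------------------------------------------
# exact-model generator


def simulate_from_hmm(
    params: ModelParams,
    site_density: float = 7_000.0,
    L: int = 100_000,
    seed: int = 0,
    fixed_fraction: float = 0.06,
    rate_cm_per_mb: float = 1.0,
    n_chrom: int = 370,
) -> tuple[SiteSequence, np.ndarray]:
    """Draw a site sequence from the HMM itself, with the true state path.

    ``site_density`` is the expected number of informative sites per cM on a
    uniform map; inter-site distances are exponential.  Each site's frequency
    class is drawn independently of the state path: fixed derived with
    probability ``fixed_fraction``, otherwise a segregating derived-allele
    count from the neutral 1/i frequency spectrum.  The archaic allele is then
    drawn from the state- and class-conditional emission distribution.
    """
    rng = np.random.default_rng(seed)
    spacing_cm = rng.exponential(1.0 / site_density, size=L)
    gpos = np.cumsum(spacing_cm)
    pos = np.round(gpos * 1e6 / rate_cm_per_mb).astype(np.int64) + 1
    prev = 0
    for i in range(L):  # nudge rounding collisions apart
        if pos[i] <= prev:
            pos[i] = prev + 1
        prev = pos[i]
    gpos = pos * rate_cm_per_mb * 1e-6

    # frequency classes: neutral SFS within segregating counts
    counts = np.arange(1, n_chrom)
    sfs = 1.0 / counts
    sfs /= sfs.sum()
    derived_count = np.where(
        rng.random(L) < fixed_fraction,
        n_chrom,
        rng.choice(counts, size=L, p=sfs),
    )

    # state path (inlined transition sampling: the 3x3 matrix has 5 free entries)
    states = np.empty(L, dtype=np.int64)
    from .model import STATE_E, STATE_ELS, STATE_I, default_init

    states[0] = rng.choice(3, p=default_init(params))
    d = np.diff(gpos)
    aI = np.exp(-d / params.l_I)
    aE = np.exp(-d / params.l_E)
    aS = np.exp(-d / params.l_ELS)
    u = rng.random(L - 1)
    pp = params.p
    prev = int(states[0])
    for i in range(1, L):
        ui = u[i - 1]
        if prev == STATE_I:
            a = aI[i - 1]
            if ui < a:
                prev = STATE_I
            elif ui < a + (1.0 - pp) * (1.0 - a):
                prev = STATE_E
            else:
                prev = STATE_ELS
        elif prev == STATE_E:
            prev = STATE_E if ui < aE[i - 1] else STATE_I
        else:
            prev = STATE_ELS if ui < aS[i - 1] else STATE_I
        states[i] = prev

    # emissions
    tmp = SiteSequence(
        pos=pos, derived_count=derived_count,
        archaic_derived=np.zeros(L, dtype=bool),
        n_chrom=n_chrom, gpos={MAP_NAME: gpos},
    )
    classes = tmp.freq_classes(params.n_bins)
    p_der = params.prob_derived()[classes, states]
    tmp.archaic_derived = rng.random(L) < p_der
    return tmp, states


# ---------------------------------------------------------------------------
# coalescent scenarios


def _external_tracts(
    ts: tskit.TreeSequence, n_modern: int, archaic_nodes: list[int]
) -> list[tuple[float, float]]:
    """Maximal intervals where every archaic lineage is external to the panel."""
    humans = list(range(n_modern))
    tracts: list[tuple[float, float]] = []
    cur_start = None
    for tree in ts.trees():
        m = tree.mrca(*humans)
        ext = all(not tree.is_descendant(a, m) for a in archaic_nodes)
        left, right = tree.interval.left, tree.interval.right
        if ext:
            if cur_start is None:
                cur_start = left
        else:
            if cur_start is not None:
                tracts.append((cur_start, left))
                cur_start = None
    if cur_start is not None:
        tracts.append((cur_start, ts.sequence_length))
    return tracts


def _sites_from_ts(
    ts: tskit.TreeSequence,
    demog: DemographyConfig,
    archaic_index: int = 0,
    chrom: str = "1",
    rng: np.random.Generator | None = None,
) -> SiteSequence:
    """Informative-site table (polymorphic or fixed derived in the panel).

    Sites with more than two alleles (recurrent mutation: a third allele) are
    disregarded, as are sites carrying no derived allele in the panel.
    """
    n = demog.n_modern
    arc = n + archaic_index
    pos_l: list[int] = []
    dc_l: list[int] = []
    ad_l: list[bool] = []
    for var in ts.variants():
        if len(var.alleles) != 2:
            continue
        g = var.genotypes
        d = int(np.count_nonzero(g[:n]))
        if d == 0:
            continue
        arc_der = bool(g[arc] != 0)
        if d == n and arc_der and not demog.include_shared_fixed:
            continue  # shared substitution: outside the human-specific catalog
        pos_l.append(int(var.site.position) + 1)  # 1-based
        dc_l.append(d)
        ad_l.append(arc_der)
    pos = np.array(pos_l, dtype=np.int64)
    ad = np.array(ad_l, dtype=bool)
    if demog.polarization_error > 0 and rng is not None:
        # mispolarized sites swap ancestral/derived; for the archaic allele the
        # observation flips, for the panel the count reflects
        flip = rng.random(len(pos)) < demog.polarization_error
        dc = np.array(dc_l, dtype=np.int64)
        dc[flip] = demog.n_modern - dc[flip]
        keep = dc >= 1
        ad = np.where(flip, ~ad, ad)[keep]
        pos, dc = pos[keep], dc[keep]
    else:
        dc = np.array(dc_l, dtype=np.int64)
    gpos = pos * demog.recomb_cm_per_mb * 1e-6
    return SiteSequence(
        pos=pos, derived_count=dc, archaic_derived=ad,
        n_chrom=n, gpos={MAP_NAME: gpos}, chrom=chrom,
    )


def _add_stem_sites(
    seq: SiteSequence,
    ts: tskit.TreeSequence,
    demog: DemographyConfig,
    rng: np.random.Generator,
) -> SiteSequence:
    """Overlay substitutions from the shared human-archaic stem.

    Data polarized against a deep outgroup contain many positions where all
    panel chromosomes and the archaic carry the derived allele: mutations that
    fixed before the human-archaic split, on the branch between the outgroup
    divergence and the local grand MRCA.  Such branches sit above the root of
    the sampled trees, so they are integrated out analytically: for every
    marginal tree, mutations are dropped as Poisson with rate ``mu *
    (T_outgroup - t_root)`` per bp and added as fixed-derived sites carrying
    the derived archaic allele.  ``T_outgroup`` is the expected human-outgroup
    MRCA (split time plus one coalescence in the root population).
    """
    t_total = demog.gens(demog.t_outgroup_split_kya) + 2.0 * demog.ne_outgroup
    taken = set(seq.pos.tolist())
    new_pos: list[int] = []
    for tree in ts.trees():
        if tree.num_roots != 1:
            continue
        stem = t_total - tree.time(tree.root)
        if stem <= 0:
            continue
        left, right = tree.interval.left, tree.interval.right
        n_mut = rng.poisson(demog.mutation_rate * stem * (right - left))
        for _ in range(n_mut):
            p = int(rng.integers(int(left), max(int(right), int(left) + 1))) + 1
            while p in taken:
                p += 1
            taken.add(p)
            new_pos.append(p)
    if not new_pos:
        return seq
    pos = np.concatenate([seq.pos, np.array(new_pos, dtype=np.int64)])
    dc = np.concatenate([seq.derived_count, np.full(len(new_pos), seq.n_chrom, dtype=np.int64)])
    ad = np.concatenate([seq.archaic_derived, np.ones(len(new_pos), dtype=bool)])
    order = np.argsort(pos)
    rate = demog.recomb_cm_per_mb * 1e-6
    return SiteSequence(
        pos=pos[order], derived_count=dc[order], archaic_derived=ad[order],
        n_chrom=seq.n_chrom, gpos={MAP_NAME: pos[order] * rate}, chrom=seq.chrom,
    )


def _label_sites(seq: SiteSequence, tracts: list[tuple[float, float]]) -> np.ndarray:
    ext = np.zeros(len(seq), dtype=bool)
    pos0 = seq.pos - 1
    for l, r in tracts:
        ext |= (pos0 >= l) & (pos0 < r)
    return ext


def _package_region(
    ts, demog, region_bp, seed, keep_ts=False, rng=None, **meta
) -> SimulatedRegion:
    arcs = [demog.n_modern + i for i in range(demog.n_archaic)]
    tracts = _external_tracts(ts, demog.n_modern, arcs)
    seq = _sites_from_ts(ts, demog, rng=rng)
    if rng is not None and demog.include_shared_fixed:
        seq = _add_stem_sites(seq, ts, demog, rng)
    return SimulatedRegion(
        seq=seq,
        external=_label_sites(seq, tracts),
        tracts=tracts,
        region_bp=region_bp,
        demog=demog,
        seed=seed,
        ts=ts if keep_ts else None,
        **meta,
    )


def simulate_neutral(
    demog: DemographyConfig | None = None,
    region_bp: int = 1_000_000,
    n_reps: int = 1,
    seed: int = 0,
    keep_ts: bool = False,
) -> list[SimulatedRegion]:
    """Neutral coalescent simulations under the split demography."""
    demog = demog or DemographyConfig()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        s1, s2 = int(rng.integers(1, 2**31 - 1)), int(rng.integers(1, 2**31 - 1))
        ts = msprime.sim_ancestry(
            samples=demog.sample_sets(),
            demography=demog.to_demography(),
            sequence_length=region_bp,
            recombination_rate=demog.recomb_per_bp,
            random_seed=s1,
            ploidy=2,
        )
        ts = msprime.sim_mutations(ts, rate=demog.mutation_rate, random_seed=s2)
        out.append(_package_region(ts, demog, region_bp, s1, keep_ts, rng))
    return out


def conditional_fixation_time(s: float, ne: float) -> float:
    """Expected fixation time (generations) of an advantageous additive allele
    conditioned on fixation (diffusion approximation; ``s`` is the heterozygote
    advantage, fitnesses 1, 1+s, 1+2s)."""
    alpha = 2.0 * ne * s
    if alpha <= 1.5:
        # near-neutral limit: conditional fixation takes ~4N generations
        return 4.0 * ne
    return 2.0 * (math.log(alpha) + np.euler_gamma) / s


def matched_age_selection(age_kya: float, demog: DemographyConfig) -> float:
    """Effective selection coefficient whose conditional fixation time equals
    the allele age — the conditioned-trajectory stand-in for a neutral allele
    that fixed within its age.

    The trajectory is simulated in the deep epoch (the conditioned process
    must complete before the recent epoch begins), so the fixation time is
    matched to ``age - t_deep``.
    """
    from scipy.optimize import brentq

    target = demog.gens(age_kya) - demog.t_deep_gens - 1.0
    if target <= 0:
        raise ValueError("allele age must exceed the recent-epoch boundary")
    f = lambda s: conditional_fixation_time(s, demog.ne_modern_deep) - target
    if f(0.5) > 0:
        raise ValueError("age too small to be matched by any plausible coefficient")
    return float(brentq(f, 1e-4, 0.5, xtol=1e-7))


def _wf_trajectory_status(
    s: float, age_gens: float, ne: float, rng: np.random.Generator
) -> tuple[str, float]:
    """Forward Wright-Fisher frequency trajectory of a new allele.

    Returns the present-day status ("fixed", "lost", "segregating") and, if
    fixed, the number of generations from origination to fixation.
    """
    n2 = int(2 * ne)
    x = 1.0 / n2
    sh = s  # heterozygote advantage, additive gene action
    for g in range(int(age_gens)):
        xsel = x * (1 + sh) / (1 + sh * x) if s > 0 else x
        x = rng.binomial(n2, min(xsel, 1.0)) / n2
        if x == 0.0:
            return "lost", math.nan
        if x == 1.0:
            return "fixed", float(g + 1)
    return "segregating", math.nan


def simulate_sweep(
    demog: DemographyConfig | None = None,
    sweep: SweepConfig | None = None,
    region_bp: int = 1_000_000,
    n_reps: int = 1,
    seed: int = 0,
    keep_ts: bool = False,
    max_retries: int = 1000,
) -> list[SimulatedRegion]:
    """Selective sweeps of given strength and mutation age on the modern branch.

    The sweep is simulated with a conditioned allele-frequency trajectory in
    the African population (two-stage: the sweep phase runs in a
    single-population model up to the archaic split; the archaic lineage is
    then merged and coalescence completes in the ancestral population).  The
    sweep completes ``conditional_fixation_time`` generations after the
    mutation age, so the beneficial mutation originates at ``age_kya``.

    With ``conditioning="any"`` a forward trajectory decides the fate of the
    allele first; lost or still-segregating alleles fall back to a neutral
    history (recorded in the region metadata).  ``s = 0`` is exactly neutral.
    """
    demog = demog or DemographyConfig()
    sweep = sweep or SweepConfig()
    if demog.n_archaic != 1:
        raise ValueError("sweep simulations support a single archaic lineage")
    rng = np.random.default_rng(seed)
    out = []
    position = sweep.position if sweep.position is not None else region_bp // 2
    age_g = demog.gens(sweep.age_kya)
    for _ in range(n_reps):
        meta = dict(selected_pos=int(position), s=sweep.s, age_kya=sweep.age_kya)
        if sweep.conditioning == "any" and sweep.s > 0:
            status, t_fix = _wf_trajectory_status(
                sweep.s, age_g, demog.ne_modern_deep, rng
            )
            meta["fixed"] = status == "fixed"
        else:
            status, t_fix = "fixed", conditional_fixation_time(
                sweep.s, demog.ne_modern_deep
            )
            meta["fixed"] = sweep.s > 0
        if sweep.s == 0 or status != "fixed":
            region = simulate_neutral(demog, region_bp, 1, int(rng.integers(1, 2**31 - 1)),
                                      keep_ts)[0]
            for k, v in meta.items():
                setattr(region, k, v)
            out.append(region)
            continue
        if not math.isfinite(t_fix):
            t_fix = conditional_fixation_time(sweep.s, demog.ne_modern_deep)
        # the sweep phase must fall inside the deep epoch
        t_end = max(age_g - t_fix, demog.t_deep_gens + 1.0)
        region = _simulate_one_sweep(
            demog, sweep.s, t_end, position, region_bp, rng, keep_ts, meta, max_retries
        )
        out.append(region)
    return out


def _simulate_one_sweep(
    demog, s, t_end, position, region_bp, rng, keep_ts, meta, max_retries
):
    """``s`` here is the heterozygote advantage; msprime's genic-selection
    parameter is the homozygote advantage, i.e. ``2 s``."""
    n2 = 2 * demog.ne_modern_deep
    model = [
        msprime.StandardCoalescent(duration=t_end),
        msprime.SweepGenicSelection(
            position=position, start_frequency=1.0 / n2,
            end_frequency=1.0 - 1.0 / n2, s=2.0 * s, dt=1e-6,
        ),
        msprime.StandardCoalescent(),
    ]
    stage1 = msprime.Demography()
    stage1.add_population(name="AFR", initial_size=demog.ne_modern)
    if demog.ne_modern_deep != demog.ne_modern:
        stage1.add_population_parameters_change(
            time=demog.t_deep_gens, population="AFR",
            initial_size=demog.ne_modern_deep,
        )
    last_err = None
    for attempt in range(max_retries):
        s1 = int(rng.integers(1, 2**31 - 1))
        s2 = int(rng.integers(1, 2**31 - 1))
        try:
            ts1 = msprime.sim_ancestry(
                samples=[msprime.SampleSet(demog.n_modern, population="AFR", ploidy=1)],
                demography=stage1,
                sequence_length=region_bp,
                recombination_rate=demog.recomb_per_bp,
                model=model,
                end_time=demog.t_split_gens,
                random_seed=s1,
                ploidy=2,
            )
            break
        except Exception as err:  # rare trajectory failures; retry with new seed
            last_err = err
    else:
        raise RuntimeError(
            f"sweep simulation failed after {max_retries} retries "
            f"(s={s}, t_end={t_end:.0f} gens): {last_err}"
        )
    tables = ts1.dump_tables()
    arc_node = tables.nodes.add_row(
        flags=tskit.NODE_IS_SAMPLE,
        time=demog.gens(demog.t_archaic_sample_kya),
        population=0,
    )
    tables.sort()
    stage2 = msprime.Demography()
    stage2.add_population(name="AFR", initial_size=demog.ne_ancestral)
    ts2 = msprime.sim_ancestry(
        initial_state=tables.tree_sequence(),
        demography=stage2,
        recombination_rate=demog.recomb_per_bp,
        start_time=demog.t_split_gens,
        random_seed=s2,
        ploidy=2,
    )
    # canonical sample order: panel chromosomes 0..n-1, then the archaic
    ts2 = ts2.simplify(samples=list(range(demog.n_modern)) + [arc_node])
    ts2 = msprime.sim_mutations(ts2, rate=demog.mutation_rate, random_seed=s2)
    return _package_region(ts2, demog, region_bp, s1, keep_ts, rng, **meta)


def simulate_neutral_fixation(
    demog: DemographyConfig | None = None,
    age_kya: float = 600.0,
    region_bp: int = 1_000_000,
    n_reps: int = 1,
    seed: int = 0,
    keep_ts: bool = False,
) -> list[SimulatedRegion]:
    """Neutral allele of the given age conditioned to have reached fixation.

    The conditioned frequency trajectory is approximated by the conditional
    sweep process with the effective coefficient from
    :func:`matched_age_selection`, i.e. the weakest selection whose conditional
    fixation time fits inside the allele's age.  The returned regions carry
    ``s = 0`` and the focal position, so the external tract around the fixed
    neutral variant can be measured directly.
    """
    demog = demog or DemographyConfig()
    s_eff = matched_age_selection(age_kya, demog)
    rng = np.random.default_rng(seed)
    age_g = demog.gens(age_kya)
    t_fix = conditional_fixation_time(s_eff, demog.ne_modern_deep)
    t_end = max(age_g - t_fix, demog.t_deep_gens + 1.0)
    position = region_bp // 2
    out = []
    for _ in range(n_reps):
        meta = dict(selected_pos=position, s=0.0, age_kya=age_kya, fixed=True)
        out.append(
            _simulate_one_sweep(
                demog, s_eff, t_end, position, region_bp, rng, keep_ts, meta, 1000
            )
        )
    return out


def simulate_background_selection_proxy(
    demog: DemographyConfig | None = None,
    del_rate: float = 1e-8,
    mean_s: float = 0.05,
    dominance: float = 0.1,
    region_bp: int = 300_000,
    n_reps: int = 1,
    seed: int = 0,
    rescale: float = 50.0,
    gamma_shape: float = 0.2,
    keep_ts: bool = False,
) -> list[SimulatedRegion]:
    """Reduced-scale forward simulation of background selection.

    Deleterious mutations arise at ``del_rate`` per bp per generation with
    gamma-distributed selection coefficients (mean ``mean_s``, shape
    ``gamma_shape``) and dominance ``dominance``; they affect fitness in a
    Wright-Fisher forward phase covering the time since the archaic split,
    with all parameters rescaled by ``rescale`` (population sizes divided,
    rates and coefficients multiplied).  Ancestral coalescence is completed
    neutrally and neutral mutations are overlaid.  The rescaling factor is
    recorded on each region's demography.
    """
    from .wrightfisher import forward_bgs_region

    demog = demog or DemographyConfig()
    rng = np.random.default_rng(seed)
    out = []
    for _ in range(n_reps):
        rep_seed = int(rng.integers(1, 2**31 - 1))
        ts, scaled = forward_bgs_region(
            demog, del_rate=del_rate, mean_s=mean_s, dominance=dominance,
            region_bp=region_bp, rescale=rescale, gamma_shape=gamma_shape,
            seed=rep_seed,
        )
        region = _package_region(ts, scaled, region_bp, rep_seed, keep_ts, rng)
        out.append(region)
    return out


@dataclass
class DetectionStudy:
    """Outcome of a sweep-detection simulation study.

    Rates are fractions in [0, 1]: ``tp_rate`` counts replicates whose
    selected variant falls inside a called ELS region; ``fp_fraction`` counts
    called regions not containing the variant, as a fraction of all called
    regions; the ``_filtered`` variants apply the minimum genetic-length
    cutoff first.
    """

    n_reps: int
    tp_rate: float
    fp_fraction: float
    tp_rate_filtered: float
    fp_fraction_filtered: float
    n_regions: int
    n_regions_filtered: int
    focal_tracts_cm: list = field(default_factory=list)
    fits: list = field(default_factory=list, repr=False)


def sweep_detection_study(
    regions: list[SimulatedRegion],
    cutoffs=None,
    min_glen: float = 0.025,
    seed: int = 0,
    n_restarts: int = 2,
    opt_max_evals: int = 400,
    max_rounds: int = 3,
) -> DetectionStudy:
    """Full detection pipeline over simulated sweep replicates.

    Each replicate is treated like a chromosome in the genome scan: the full
    model is fitted to its site table (Baum-Welch emissions + length
    optimization, multiple starts), the ELS posterior is decoded and candidate
    regions are called with the standard posterior cutoffs, then filtered on
    genetic length under the uniform simulation map.
    """
    from .inference import fit
    from .model import forward_backward
    from .segments import CutoffConfig, call_segments

    cutoffs = cutoffs or CutoffConfig(min_glen_autosome=min_glen)
    n_det = n_det_f = n_reg = n_fp = n_reg_f = n_fp_f = 0
    focals = []
    fits = []
    for k, region in enumerate(regions):
        res = fit(
            region.seq, n_restarts=n_restarts, refine=False,
            seed=seed + 17 * k, opt_max_evals=opt_max_evals,
            max_rounds=max_rounds,
        )
        fits.append(res)
        track = forward_backward(region.seq, res.params)
        segs = call_segments(track, region.seq, cutoffs)
        rate = region.demog.recomb_cm_per_mb * 1e-6
        target = region.selected_pos + 1 if region.selected_pos is not None else None
        hit = [s for s in segs if target is not None and s.contains(target)]
        n_det += bool(hit)
        n_reg += len(segs)
        n_fp += len(segs) - len(hit)
        filt = [s for s in segs if (s.end - s.start) * rate >= min_glen]
        hit_f = [s for s in filt if target is not None and s.contains(target)]
        n_det_f += bool(hit_f)
        n_reg_f += len(filt)
        n_fp_f += len(filt) - len(hit_f)
        focals.append(region.focal_tract_cm() or 0.0)
    n = len(regions)
    return DetectionStudy(
        n_reps=n,
        tp_rate=n_det / n if n else math.nan,
        fp_fraction=n_fp / n_reg if n_reg else 0.0,
        tp_rate_filtered=n_det_f / n if n else math.nan,
        fp_fraction_filtered=n_fp_f / n_reg_f if n_reg_f else 0.0,
        n_regions=n_reg,
        n_regions_filtered=n_reg_f,
        focal_tracts_cm=focals,
        fits=fits,
    )


def measured_emissions(
    regions: list[SimulatedRegion], n_bins: int = 20
) -> dict[str, np.ndarray | float]:
    """Emission probabilities measured directly from the true genealogy labels.

    Pools sites across regions and returns, with the parameter naming of
    :class:`~elscan.model.ModelParams`: ``eps_I`` (ancestral archaic allele at
    fixed sites in internal regions), ``theta_E_fix`` (derived archaic allele
    at fixed sites in external regions), ``theta_I`` per frequency bin
    (derived archaic allele at segregating sites in internal regions; NaN for
    empty bins) and ``eps_E_obs`` (the realized external-state error rate at
    segregating sites).
    """
    agg_fix_int = np.zeros(2)  # [total, ancestral]
    agg_fix_ext = np.zeros(2)  # [total, derived]
    agg_seg_ext = np.zeros(2)  # [total, derived]
    theta_num = np.zeros(n_bins)
    theta_den = np.zeros(n_bins)
    for region in regions:
        seq, ext = region.seq, region.external
        cls = seq.freq_classes(n_bins)
        der = seq.archaic_derived
        fixed = cls == n_bins
        agg_fix_int += [np.sum(fixed & ~ext), np.sum(fixed & ~ext & ~der)]
        agg_fix_ext += [np.sum(fixed & ext), np.sum(fixed & ext & der)]
        agg_seg_ext += [np.sum(~fixed & ext), np.sum(~fixed & ext & der)]
        for b in range(n_bins):
            m = (cls == b) & ~ext
            theta_den[b] += m.sum()
            theta_num[b] += np.sum(m & der)
    with np.errstate(invalid="ignore"):
        theta = np.where(theta_den > 0, theta_num / np.maximum(theta_den, 1), np.nan)
    return {
        "eps_I": agg_fix_int[1] / agg_fix_int[0] if agg_fix_int[0] else float("nan"),
        "theta_E_fix": agg_fix_ext[1] / agg_fix_ext[0] if agg_fix_ext[0] else float("nan"),
        "theta_I": theta,
        "theta_I_counts": theta_den,
        "eps_E_obs": agg_seg_ext[1] / agg_seg_ext[0] if agg_seg_ext[0] else float("nan"),
    }


# ---------------------------------------------------------------------------
# detection accounting


@dataclass
class DetectionSummary:
    """True/false-positive accounting for sweep-detection simulations."""

    n_reps: int
    n_detected: int
    n_regions: int
    n_false_regions: int
    roc: list[tuple[float, float, float]] = field(default_factory=list)

    @property
    def tp_rate(self) -> float:
        return self.n_detected / self.n_reps if self.n_reps else math.nan

    @property
    def fp_rate(self) -> float:
        return self.n_false_regions / self.n_regions if self.n_regions else 0.0


def evaluate_detection(
    regions: list[SimulatedRegion],
    calls: list[list],
    min_glen: float | None = None,
    tracks: list | None = None,
    cutoffs: np.ndarray | None = None,
) -> DetectionSummary:
    """Score called candidate regions against the simulated truth.

    A replicate counts as detected (TP) when one of its called regions
    contains the selected variant; called regions not containing it count as
    false-positive regions.  With ``min_glen`` the calls are first filtered on
    genetic length under the uniform simulation map.  When per-site posterior
    ``tracks`` are given, a per-site ROC over posterior cutoffs is added
    (sites inside the true selected external tract are positives).
    """
    if len(calls) != len(regions):
        raise ValueError("one call list per simulated region required")
    n_det = n_reg = n_fp = 0
    for region, segs in zip(regions, calls):
        if min_glen is not None:
            rate = region.demog.recomb_cm_per_mb * 1e-6
            segs = [s for s in segs if (s.end - s.start) * rate >= min_glen]
        n_reg += len(segs)
        hit = [
            s for s in segs
            if region.selected_pos is not None and s.contains(region.selected_pos + 1)
        ]
        n_fp += len(segs) - len(hit)
        if hit:
            n_det += 1
    roc = []
    if tracks is not None:
        cutoffs = np.arange(0.05, 1.0, 0.05) if cutoffs is None else cutoffs
        truth = np.concatenate([r.true_els_site_mask() for r in regions])
        post = np.concatenate([t.p_els for t in tracks])
        pos, neg = truth.sum(), (~truth).sum()
        for c in cutoffs:
            called = post >= c
            tpr = (called & truth).sum() / pos if pos else math.nan
            fpr = (called & ~truth).sum() / neg if neg else math.nan
            roc.append((float(c), float(tpr), float(fpr)))
    return DetectionSummary(
        n_reps=len(regions), n_detected=n_det, n_regions=n_reg,
        n_false_regions=n_fp, roc=roc,
    )
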