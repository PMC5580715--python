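"""Wright-Fisher forward engine with tskit ancestry recording.

Supports the reduced-scale background-selection proxy: diploid populations
evolve forward in time with recombination and deleterious mutations
(gamma-distributed selection coefficients, partial dominance) that affect
fitness but are tracked only as bookkeeping — the recorded tree sequence holds
ancestry alone.  After the forward phase the tables are simplified to the
sampled chromosomes, ancestral coalescence is completed neutrally with msprime
(recapitation) and neutral mutations are overlaid.

Population-size rescaling by a factor ``Q`` (sizes divided by Q; per-generation
rates, selection coefficients and times multiplied/divided accordingly) keeps
the products ``N*s``, ``N*r``, ``N*mu`` of the target model while making the
forward phase tractable at desk scale.
"""

from __future__ import annotations

from dataclasses import replace

import msprime
import numpy as np
import tskit


class _Registry:
    """Deleterious-mutation registry: position and selection coefficient."""

    def __init__(self):
        self.pos: list[float] = []
        self.s: list[float] = []

    def add(self, pos: float, s: float) -> int:
        self.pos.append(pos)
        self.s.append(s)
        return len(self.pos) - 1

    def arrays(self):
        return np.asarray(self.pos), np.asarray(self.s)


class _Population:
    """One diploid population: genome node ids and per-genome mutation lists."""

    def __init__(self, n_diploids: int, tables: tskit.TableCollection, time: float):
        self.n = n_diploids
        self.ids = np.array(
            [tables.nodes.add_row(time=time, population=0) for _ in range(2 * n_diploids)],
            dtype=np.int64,
        )
        self.muts: list[np.ndarray] = [
            np.empty(0, dtype=np.int64) for _ in range(2 * n_diploids)
        ]

    def fitness(self, s_arr: np.ndarray, h: float) -> np.ndarray:
        w = np.ones(self.n)
        for i in range(self.n):
            a, b = self.muts[2 * i], self.muts[2 * i + 1]
            if a.size == 0 and b.size == 0:
                continue
            hom = np.intersect1d(a, b, assume_unique=False)
            het = np.setxor1d(a, b, assume_unique=False)
            w[i] = np.prod(1.0 - s_arr[hom]) * np.prod(1.0 - h * s_arr[het])
        return np.maximum(w, 0.0)


def _gamete(
    pop: _Population,
    parent: int,
    tables: tskit.TableCollection,
    time: float,
    L: float,
    r_per_bp: float,
    registry_pos: np.ndarray,
    rng: np.random.Generator,
) -> tuple[int, np.ndarray]:
    """Meiosis: recombine the parent's two genomes, record edges, return the
    child node id and the deleterious mutations inherited."""
    child = tables.nodes.add_row(time=time, population=0)
    g = (pop.ids[2 * parent], pop.ids[2 * parent + 1])
    m = (pop.muts[2 * parent], pop.muts[2 * parent + 1])
    nbreaks = rng.poisson(r_per_bp * L)
    phase = rng.integers(0, 2)
    if nbreaks == 0:
        tables.edges.add_row(0.0, L, parent=g[phase], child=child)
        return child, m[phase]
    breaks = np.unique(rng.uniform(0.0, L, size=nbreaks))
    bounds = np.concatenate([[0.0], breaks, [L]])
    inherited = []
    for k in range(len(bounds) - 1):
        src = (phase + k) % 2
        left, right = bounds[k], bounds[k + 1]
        tables.edges.add_row(left, right, parent=g[src], child=child)
        mm = m[src]
        if mm.size:
            p = registry_pos[mm]
            inherited.append(mm[(p >= left) & (p < right)])
    if inherited:
        out = np.concatenate(inherited)
        out.sort()
        return child, out
    return child, np.empty(0, dtype=np.int64)


def run_forward(
    pop_sizes: dict[str, int],
    n_gens: int,
    region_bp: float,
    recomb_per_bp: float,
    seed: int,
    del_rate_per_genome: float = 0.0,
    mean_s: float = 0.0,
    gamma_shape: float = 0.2,
    dominance: float = 0.1,
    s_cap: float = 1.0,
    archaic_pop: str | None = None,
    archaic_sample_gen: int | None = None,
    simplify_interval: int = 25,
    size_changes: dict[int, dict[str, int]] | None = None,
) -> tuple[tskit.TableCollection, dict[str, np.ndarray], int | None]:
    """Run the forward phase and return tables, final genome ids per population
    and the retained archaic genome node (if requested).

    Node times count down from ``n_gens`` (founders) to 0 (final generation),
    so the tables can be handed to msprime for recapitation of the founder
    roots.  Populations never exchange migrants; shared ancestry is supplied by
    recapitation.
    """
    rng = np.random.default_rng(seed)
    tables = tskit.TableCollection(sequence_length=float(region_bp))
    tables.time_units = "generations"
    tables.populations.metadata_schema = tskit.MetadataSchema.permissive_json()
    tables.populations.add_row(metadata={"name": "pop_0"})
    registry = _Registry()
    pops = {name: _Population(n, tables, float(n_gens)) for name, n in pop_sizes.items()}
    size_changes = size_changes or {}
    archaic_node: int | None = None

    for gen in range(1, n_gens + 1):
        time = float(n_gens - gen)
        reg_pos, reg_s = registry.arrays()
        targets = size_changes.get(gen, {})
        for name, pop in pops.items():
            n_parents = pop.n
            n_off = targets.get(name, n_parents)
            if del_rate_per_genome > 0 and reg_s.size:
                w = pop.fitness(reg_s, dominance)
                tot = w.sum()
                probs = w / tot if tot > 0 else None
            else:
                probs = None
            parents = rng.choice(n_parents, size=(n_off, 2), p=probs)
            new_ids = np.empty(2 * n_off, dtype=np.int64)
            new_muts: list[np.ndarray] = [None] * (2 * n_off)  # type: ignore
            for j in range(n_off):
                for k in range(2):
                    node, inher = _gamete(
                        pop, int(parents[j, k]), tables, time, region_bp,
                        recomb_per_bp, reg_pos, rng,
                    )
                    n_new = rng.poisson(del_rate_per_genome) if del_rate_per_genome > 0 else 0
                    if n_new:
                        fresh = [
                            registry.add(
                                rng.uniform(0.0, region_bp),
                                min(rng.gamma(gamma_shape, mean_s / gamma_shape), s_cap),
                            )
                            for _ in range(n_new)
                        ]
                        inher = np.concatenate([inher, np.array(fresh, dtype=np.int64)])
                    new_ids[2 * j + k] = node
                    new_muts[2 * j + k] = inher
            pop.ids, pop.muts, pop.n = new_ids, new_muts, n_off
            # refresh the registry arrays so new mutations are inheritable
            reg_pos, reg_s = registry.arrays()
        if archaic_pop is not None and gen == archaic_sample_gen:
            archaic_node = int(pops[archaic_pop].ids[0])
        if gen % simplify_interval == 0 or gen == n_gens:
            keep = np.concatenate(
                [p.ids for p in pops.values()]
                + ([np.array([archaic_node])] if archaic_node is not None else [])
            )
            tables.sort()
            node_map = tables.simplify(
                samples=keep.astype(np.int32), keep_input_roots=True,
                filter_sites=False,
            )
            for pop in pops.values():
                pop.ids = node_map[pop.ids]
            if archaic_node is not None:
                archaic_node = int(node_map[archaic_node])
    return tables, {name: p.ids for name, p in pops.items()}, archaic_node


def _finalize(
    tables: tskit.TableCollection,
    sample_nodes: np.ndarray,
    ne_recap: float,
    recomb_per_bp: float,
    mut_rate: float,
    seed: int,
) -> tskit.TreeSequence:
    """Simplify to the samples, recapitate founder roots, overlay mutations."""
    tables.sort()
    tables.simplify(samples=sample_nodes.astype(np.int32), keep_input_roots=True)
    flags = tables.nodes.flags
    flags[: len(sample_nodes)] |= tskit.NODE_IS_SAMPLE
    tables.nodes.flags = flags
    ts = tables.tree_sequence()
    ts = msprime.sim_ancestry(
        initial_state=ts,
        population_size=ne_recap,
        recombination_rate=recomb_per_bp,
        random_seed=seed,
        ploidy=2,
    )
    return msprime.sim_mutations(ts, rate=mut_rate, random_seed=seed + 1)


def forward_bgs_region(
    demog,
    del_rate: float,
    mean_s: float,
    dominance: float,
    region_bp: int,
    rescale: float,
    gamma_shape: float,
    seed: int,
):
    """Two-population forward phase since the archaic split, under background
    selection, rescaled by ``rescale``; returns the mutated tree sequence and
    the demography config used for reporting (original genetic-map units)."""
    q = float(rescale)
    half_panel = demog.n_modern // 2 + demog.n_modern % 2
    n_mod_deep = max(int(round(demog.ne_modern_deep / q)), half_panel)
    n_mod_recent = max(int(round(demog.ne_modern / q)), half_panel)
    n_arc = max(int(round(demog.ne_archaic / q)), 2)
    n_gens = max(int(round(demog.t_split_gens / q)), 2)
    arc_gen = n_gens - int(round(demog.gens(demog.t_archaic_sample_kya) / q))
    arc_gen = min(max(arc_gen, 1), n_gens)
    deep_boundary_gen = n_gens - int(round(demog.t_deep_gens / q))
    size_changes = {}
    if 1 <= deep_boundary_gen <= n_gens and n_mod_recent != n_mod_deep:
        size_changes[deep_boundary_gen] = {"modern": n_mod_recent}
    r_scaled = demog.recomb_per_bp * q
    tables, final_ids, arc_node = run_forward(
        pop_sizes={"modern": n_mod_deep, "archaic": n_arc},
        n_gens=n_gens,
        region_bp=region_bp,
        recomb_per_bp=r_scaled,
        seed=seed,
        del_rate_per_genome=del_rate * q * region_bp,
        mean_s=min(mean_s * q, 1.0),
        gamma_shape=gamma_shape,
        dominance=dominance,
        archaic_pop="archaic",
        archaic_sample_gen=arc_gen,
        size_changes=size_changes,
    )
    if arc_node is None:
        raise RuntimeError("archaic lineage was not sampled during the forward phase")
    modern = final_ids["modern"][: demog.n_modern]
    if len(modern) < demog.n_modern:
        raise ValueError(
            f"rescaled modern population ({len(final_ids['modern'])} genomes) smaller "
            f"than the panel ({demog.n_modern}); lower the rescale factor"
        )
    samples = np.concatenate([modern, [arc_node]])
    ts = _finalize(
        tables, samples,
        ne_recap=demog.ne_ancestral / q,
        recomb_per_bp=r_scaled,
        mut_rate=demog.mutation_rate * q,
        seed=seed,
    )
    # report config in the rescaled time units (node times are scaled
    # generations, per-generation rates multiplied by Q) but the original
    # genetic-map units: bp positions are unscaled, so the original cM/Mb
    # applies when converting tract lengths to cM
    report = replace(
        demog,
        ne_modern=demog.ne_modern / q,
        ne_modern_deep=demog.ne_modern_deep / q,
        ne_archaic=demog.ne_archaic / q,
        ne_ancestral=demog.ne_ancestral / q,
        ne_outgroup=demog.ne_outgroup / q,
        t_split_kya=demog.t_split_kya / q,
        t_deep_kya=demog.t_deep_kya / q,
        t_archaic_sample_kya=demog.t_archaic_sample_kya / q,
        t_outgroup_split_kya=demog.t_outgroup_split_kya / q,
        mutation_rate=demog.mutation_rate * q,
    )
    return ts, report


def forward_neutral_diversity_check(
    n_diploids: int,
    region_bp: float,
    n_gens: int,
    recomb_per_bp: float,
    seed: int,
) -> float:
    """Mean pairwise branch-length diversity of a neutral single-population
    forward run (coalescent expectation: ``4 * n_diploids`` generations).

    Founder roots still uncoalesced after ``n_gens`` are completed by
    recapitation at the same population size, so the statistic tests the drift
    behaviour of the forward engine itself once ``n_gens >> 2 * n_diploids``.
    """
    tables, final_ids, _ = run_forward(
        pop_sizes={"pop": n_diploids},
        n_gens=n_gens,
        region_bp=region_bp,
        recomb_per_bp=recomb_per_bp,
        seed=seed,
    )
    ts = _finalize(
        tables, final_ids["pop"], ne_recap=n_diploids,
        recomb_per_bp=recomb_per_bp, mut_rate=0.0, seed=seed + 1,
    )
    return float(ts.diversity(mode="branch"))
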