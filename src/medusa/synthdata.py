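"""Synthetic multi-study cohorts with known ground truth for every pipeline stage.

The generators emulate the structure of real shotgun gut-metagenome
studies at desk scale: reference genomes partitioned into genes, reads
drawn from genomes proportionally to a planted community composition
with substitution errors and a two-state quality model, a small host
contamination fraction, genus-driven cluster structure for enterotype
analysis, and multi-study gene sets with planted sharing patterns.
Every generator is seed-deterministic and returns a :class:`TruthSet`
recording what was planted, so recovery can be asserted exactly.

What the generator does *not* emulate: indel sequencing errors (the
substitution-only model keeps the exact-seed test aligner sufficient),
platform-specific quality profiles, strain-level variation within a
species, and abundance distributions fitted to real cohorts.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .model import AbundanceTable, ReferenceCatalogue, SampleMap

_BASES = np.frombuffer(b"ACGT", dtype=np.uint8)


@dataclass
class TruthSet:
    """Planted ground truth emitted alongside every fixture."""

    composition: dict[str, dict[str, float]] = field(default_factory=dict)  # sample -> species -> read fraction
    genus_composition: dict[str, dict[str, float]] = field(default_factory=dict)
    core_genes: set[str] = field(default_factory=set)
    study_membership: dict[str, frozenset] = field(default_factory=dict)  # gene -> studies
    venn_sizes: dict[frozenset, int] = field(default_factory=dict)
    cluster_labels: dict[str, int] = field(default_factory=dict)  # sample -> enterotype
    host_fraction: float = 0.0
    seeds: dict[str, int] = field(default_factory=dict)


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return _BASES[rng.integers(0, 4, size=length)].tobytes().decode()


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    if rate <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    hits = np.flatnonzero(rng.random(len(arr)) < rate)
    for i in hits:
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


def _mutate_exact(rng: np.random.Generator, seq: str, n_subs: int) -> str:
    """Substitute exactly ``n_subs`` distinct positions.

    Two copies made this way differ at <= 2 * n_subs positions, so a
    per-copy budget of rate * len keeps pairwise divergence within
    2 * rate by construction.
    """
    if n_subs <= 0:
        return seq
    arr = np.frombuffer(seq.encode(), dtype=np.uint8).copy()
    for i in rng.choice(len(arr), size=min(n_subs, len(arr)), replace=False):
        choices = _BASES[_BASES != arr[i]]
        arr[i] = choices[rng.integers(0, 3)]
    return arr.tobytes().decode()


# ---------------------------------------------------------------------------
# References


def make_references(
    n_species: int = 20,
    n_genes_per_species: int = 10,
    gene_len: int = 500,
    genome_len: int | None = None,
    species_per_genus: int = 2,
    host_len: int = 20_000,
    seed: int = 0,
) -> tuple[ReferenceCatalogue, TruthSet]:
    """Random reference genomes, each the concatenation of its genes.

    Each species genome is one contig built from ``n_genes_per_species``
    genes of ``gene_len`` bases (padded with random intergenic sequence
    up to ``genome_len`` if given), so reads simulated from genomes also
    align to the gene catalogue when they fall wholly inside a gene.
    Species are grouped into genera (``species_per_genus`` each) and a
    single-phylum lineage is assigned. A host sequence of ``host_len``
    bases is included under kind ``host``.
    """
    rng = np.random.default_rng(seed)
    sequences: dict[str, str] = {}
    feature_to_group: dict[str, str] = {}
    group_to_lineage: dict[str, tuple[str, str, str]] = {}
    feature_kind: dict[str, str] = {}
    gene_to_ko: dict[str, frozenset] = {}

    for si in range(n_species):
        species = f"species{si:03d}"
        genus = f"genus{si // species_per_genus:03d}"
        group_to_lineage[species] = (species, genus, "phylum000")
        genes = []
        for gi in range(n_genes_per_species):
            gid = f"{species}.gene{gi:03d}"
            gseq = _random_seq(rng, gene_len)
            sequences[gid] = gseq
            feature_to_group[gid] = species
            feature_kind[gid] = "gene"
            gene_to_ko[gid] = frozenset({f"K{gi:05d}"})
            genes.append(gseq)
        contig = "".join(genes)
        if genome_len is not None and genome_len > len(contig):
            contig += _random_seq(rng, genome_len - len(contig))
        cid = f"{species}.contig"
        sequences[cid] = contig
        feature_to_group[cid] = species
        feature_kind[cid] = "contig"

    hid = "host.chr1"
    sequences[hid] = _random_seq(rng, host_len)
    feature_kind[hid] = "host"

    cat = ReferenceCatalogue(
        sequences=sequences,
        feature_to_group=feature_to_group,
        group_to_lineage=group_to_lineage,
        gene_to_ko=gene_to_ko,
        feature_kind=feature_kind,
    )
    truth = TruthSet(seeds={"references": seed})
    return cat, truth


# ---------------------------------------------------------------------------
# Read simulation


def simulate_run(
    refs: ReferenceCatalogue,
    composition: dict[str, float],
    n_reads: int = 10_000,
    read_len: int = 70,
    sub_error_rate: float = 0.005,
    host_fraction: float = 0.00023,
    frac_bad_reads: float = 0.02,
    good_q: int = 38,
    bad_q: int = 8,
    seed: int = 0,
    out_path: str | Path | None = None,
    run_id: str = "run",
):
    """Simulate one sequencing run from planted species abundances.

    Reads are drawn from species contigs with probability proportional
    to composition x contig length, start positions uniform,
    substitution errors at ``sub_error_rate`` per base. Host reads are a
    binomial fraction ``host_fraction`` of the total. Qualities follow a
    two-state model: most reads are uniformly ``good_q``; a fraction
    ``frac_bad_reads`` are degraded reads in which each base is bad
    (``bad_q``) with probability 0.5, which makes them fail the default
    80 %-of-bases-at-Q20 rule more often than not.

    Returns ``(records, truth)`` where records is a list of
    (id, seq, qual); with ``out_path`` the FASTQ (optionally ``.gz``) is
    written instead and the path returned.
    """
    rng = np.random.default_rng(seed)
    species = sorted(composition)
    contigs = {s: refs.sequences[f"{s}.contig"] for s in species}
    w = np.array([composition[s] * len(contigs[s]) for s in species], float)
    if w.sum() <= 0:
        raise ValueError("composition has no mass")
    p = w / w.sum()

    n_host = int(rng.binomial(n_reads, host_fraction)) if host_fraction > 0 else 0
    n_micro = n_reads - n_host
    host_seq = next(iter(refs.subset("host").values()), None)
    if n_host and host_seq is None:
        raise ValueError("host_fraction > 0 but catalogue has no host sequence")

    sources = rng.choice(len(species), size=n_micro, p=p)
    is_host = np.zeros(n_reads, bool)
    is_host[rng.choice(n_reads, size=n_host, replace=False)] = True

    truth = TruthSet(host_fraction=host_fraction, seeds={"run": seed})
    comp = {species[i]: 0 for i in range(len(species))}
    records = []
    micro_i = 0
    lineages = refs.group_to_lineage
    genus_counts: dict[str, int] = {}
    for ri in range(n_reads):
        if is_host[ri]:
            src_seq = host_seq
            label = "host"
        else:
            s = species[sources[micro_i]]
            micro_i += 1
            src_seq = contigs[s]
            comp[s] += 1
            g = lineages[s][1]
            genus_counts[g] = genus_counts.get(g, 0) + 1
            label = s
        start = int(rng.integers(0, len(src_seq) - read_len + 1))
        seq = _mutate(rng, src_seq[start : start + read_len], sub_error_rate)
        if rng.random() < frac_bad_reads:
            qarr = np.where(rng.random(read_len) < 0.5, bad_q, good_q)
        else:
            qarr = np.full(read_len, good_q)
        qual = (qarr + 33).astype(np.uint8).tobytes().decode()
        records.append((f"{run_id}.{ri}:{label}", seq, qual))

    tot = max(micro_i, 1)
    truth.composition[run_id] = {s: c / tot for s, c in comp.items()}
    truth.genus_composition[run_id] = {g: c / tot for g, c in genus_counts.items()}

    if out_path is not None:
        out_path = Path(out_path)
        opener = __import__("gzip").open if str(out_path).endswith(".gz") else open
        with opener(out_path, "wt") as fh:
            for rid, seq, qual in records:
                fh.write(f"@{rid}\n{seq}\n+\n{qual}\n")
        return out_path, truth
    return records, truth


def make_community_compositions(
    refs: ReferenceCatalogue,
    n_samples: int = 20,
    n_core_species: int = 8,
    core_min_abund: float = 0.02,
    variable_prevalence: float = 0.2,
    seed: int = 0,
) -> tuple[dict[str, dict[str, float]], TruthSet]:
    """Per-sample species compositions with a planted core.

    The first ``n_core_species`` species are present in every sample at
    abundance >= ``core_min_abund`` (their genes are the planted core);
    the remaining species each appear in a ``variable_prevalence``
    fraction of samples. Compositions are Dirichlet-perturbed around
    those presence patterns and sum to 1.
    """
    rng = np.random.default_rng(seed)
    species = sorted(refs.group_to_lineage)
    core = species[:n_core_species]
    rest = species[n_core_species:]
    comps: dict[str, dict[str, float]] = {}
    for i in range(n_samples):
        sample = f"S{i:03d}"
        present = list(core)
        for s in rest:
            if rng.random() < variable_prevalence:
                present.append(s)
        w = rng.dirichlet(np.full(len(present), 2.0))
        # guarantee the floor on core species, then renormalise
        w = np.maximum(w, [core_min_abund * 2 if s in core else 0.0 for s in present])
        w = w / w.sum()
        comps[sample] = dict(zip(present, w))
    truth = TruthSet(seeds={"cohort": seed})
    truth.core_genes = {
        gid for gid, sp in refs.feature_to_group.items()
        if sp in set(core) and refs.feature_kind.get(gid) == "gene"
    }
    truth.composition = {k: dict(v) for k, v in comps.items()}
    return comps, truth


# ---------------------------------------------------------------------------
# Enterotype cohorts


def make_enterotype_cohort(
    k: int = 3,
    n_samples: int = 60,
    n_genera: int = 73,
    driver_strength: float = 12.0,
    dirichlet_conc: float = 0.3,
    seed: int = 0,
) -> tuple[AbundanceTable, TruthSet]:
    """Genus abundance cohort with k planted, driver-genus-led clusters.

    Each cluster is a Dirichlet component with concentration
    ``dirichlet_conc`` on every genus except one distinct driver genus
    whose concentration is ``driver_strength`` — giving the driver a
    mean share of roughly driver/(driver + conc * (G-1)), comparable to
    the dominance the classical gut enterotype drivers show. Samples
    are assigned to components in balanced round-robin order.
    """
    if k > n_genera:
        raise ValueError("need at least one distinct driver genus per cluster")
    rng = np.random.default_rng(seed)
    genera = [f"genus{g:03d}" for g in range(n_genera)]
    alpha = np.full((k, n_genera), dirichlet_conc)
    for c in range(k):
        alpha[c, c] = driver_strength
    labels = np.arange(n_samples) % k
    data = np.empty((n_genera, n_samples))
    for j in range(n_samples):
        data[:, j] = rng.dirichlet(alpha[labels[j]])
    samples = [f"S{j:03d}" for j in range(n_samples)]
    table = AbundanceTable(
        pd.DataFrame(data, index=genera, columns=samples),
        denominator_policy="synthetic",
    )
    truth = TruthSet(
        cluster_labels={s: int(l) + 1 for s, l in zip(samples, labels)},
        seeds={"enterotype_cohort": seed},
    )
    return table, truth


# ---------------------------------------------------------------------------
# Multi-study gene sets


def make_multistudy_genes(
    n_core: int = 40,
    n_shared_pairs: int = 10,
    n_unique_per_study: int = 25,
    mutation_rate: float = 0.02,
    gene_len_range: tuple[int, int] = (300, 900),
    studies: Sequence[str] = ("HMP", "MetaHIT", "China", "Sweden"),
    seed: int = 0,
) -> tuple[dict[str, dict[str, str]], TruthSet]:
    """Per-study gene FASTA contents with a planted sharing (Venn) structure.

    ``n_core`` genes occur in every study, ``n_shared_pairs`` genes in
    each unordered study pair, and ``n_unique_per_study`` genes in one
    study only; shared copies carry substitutions at ``mutation_rate``
    (below the 5 % clustering radius, so planted groups stay together).
    Returns ``({study: {gene_id: seq}}, truth)`` with the exact expected
    Venn region sizes recorded.
    """
    rng = np.random.default_rng(seed)
    out: dict[str, dict[str, str]] = {s: {} for s in studies}
    truth = TruthSet(seeds={"multistudy": seed})

    def glen() -> int:
        return int(rng.integers(gene_len_range[0], gene_len_range[1] + 1))

    all_set = frozenset(studies)
    for i in range(n_core):
        base = _random_seq(rng, glen())
        gid = f"core{i:04d}"
        for st in studies:
            out[st][gid] = _mutate_exact(rng, base, int(mutation_rate * len(base)))
        truth.study_membership[gid] = all_set
    if n_core:
        truth.venn_sizes[all_set] = n_core

    pairs = [
        (a, b) for ai, a in enumerate(studies) for b in list(studies)[ai + 1 :]
    ]
    for a, b in pairs:
        key = frozenset({a, b})
        for i in range(n_shared_pairs):
            base = _random_seq(rng, glen())
            gid = f"pair.{a}.{b}.{i:04d}"
            out[a][gid] = _mutate_exact(rng, base, int(mutation_rate * len(base)))
            out[b][gid] = _mutate_exact(rng, base, int(mutation_rate * len(base)))
            truth.study_membership[gid] = key
        if n_shared_pairs:
            truth.venn_sizes[key] = n_shared_pairs
    for st in studies:
        key = frozenset({st})
        for i in range(n_unique_per_study):
            gid = f"uniq.{st}.{i:04d}"
            out[st][gid] = _random_seq(rng, glen())
            truth.study_membership[gid] = key
        if n_unique_per_study:
            truth.venn_sizes[key] = n_unique_per_study
    return out, truth


# ---------------------------------------------------------------------------
# Cohort-level convenience: runs + mapping files


def simulate_cohort_runs(
    refs: ReferenceCatalogue,
    compositions: dict[str, dict[str, float]],
    out_dir: str | Path,
    n_reads: int = 10_000,
    seed: int = 0,
    **run_kwargs,
) -> tuple[list[Path], SampleMap, dict[str, TruthSet]]:
    """One FASTQ run per sample plus the run -> sample mapping."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    sm = SampleMap()
    paths = []
    truths = {}
    for i, (sample, comp) in enumerate(compositions.items()):
        run = f"{sample}_r1"
        path, truth = simulate_run(
            refs,
            comp,
            n_reads=n_reads,
            seed=int(np.random.SeedSequence([seed, i]).generate_state(1)[0] % (2**31)),
            out_path=out_dir / f"{run}.fastq",
            run_id=run,
            **run_kwargs,
        )
        sm.run_to_sample[run] = sample
        sm.sample_to_subject[sample] = sample
        sm.sample_to_visit[sample] = 1
        paths.append(path)
        truths[sample] = truth
    return paths, sm, truths
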