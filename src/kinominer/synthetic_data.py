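"""Synthetic inputs with known truth for exercising the whole pipeline.

Two generators stand in for the external resources a real kinome screen
needs: a proteome generator that plants mutated copies of per-group
consensus domains inside random flanks (plus non-kinase decoys), and a
count-matrix generator producing Poisson-distributed RNA-seq counts across
developmental stages and stressor contrasts with known expressed/DE truth.

The per-group consensus domains and the seed alignment are fixed synthetic
fixtures shipped with the package (``data/synthetic_group_consensi.fasta``,
``data/synthetic_kinase_seed.aln.fasta``); the ten consensi are mutually
<= 60% identical so group identity stays recoverable by homology.

Everything is deterministic for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .expression_mining import DEResult
from .io_formats import (
    AMINO_ACIDS,
    KINASE_GROUPS,
    Classification,
    CountMatrix,
    ProteinRecord,
    ReferenceKinase,
    read_alignment,
    read_fasta,
)

#: Developmental stages of the count generator, in temporal order, with the
#: fraction of genes expressed at each (the study conditions emulated).
DEFAULT_STAGE_EXPRESSED_FRACTIONS: dict[str, float] = {
    "egg": 0.70,
    "cleavage": 0.74,
    "gastrulation": 0.77,
    "trochophore": 0.83,
    "d_larva": 0.88,
    "umbo": 0.90,
    "pediveliger": 0.91,
    "spat": 0.91,
    "juvenile": 0.93,
}

#: Environmental stressors of the count generator.
DEFAULT_STRESSORS = (
    "air", "temperature", "salinity",
    "cadmium", "copper", "mercury", "lead", "zinc",
)

#: Fraction of genes expressed in adult stressor-experiment controls.
ADULT_EXPRESSED_FRACTION = 0.90


def _data_path(name: str):
    return resources.files("kinominer.data").joinpath(name)


def group_consensi() -> dict[str, str]:
    """The shipped synthetic consensus domain of each kinase group."""
    with resources.as_file(_data_path("synthetic_group_consensi.fasta")) as p:
        return {r.id: r.sequence for r in read_fasta(p)}


def seed_alignment() -> tuple[list[str], list[str]]:
    """The shipped synthetic seed alignment (ids, aligned rows)."""
    with resources.as_file(_data_path("synthetic_kinase_seed.aln.fasta")) as p:
        return read_alignment(p)


# ---------------------------------------------------------------------------
# proteomes
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class PlantedDomain:
    protein_id: str
    start: int
    end: int
    group: str
    family: str


@dataclass
class ProteomeTruth:
    records: list[ProteinRecord]
    truth: list[PlantedDomain]
    decoy_ids: list[str]


def _random_sequence(rng: np.random.Generator, length: int) -> str:
    return "".join(AMINO_ACIDS[i] for i in rng.integers(20, size=length))


def _mutate(rng: np.random.Generator, seq: str, rate: float) -> str:
    out = list(seq)
    for i, a in enumerate(out):
        if rng.random() < rate:
            choices = [b for b in AMINO_ACIDS if b != a]
            out[i] = choices[rng.integers(len(choices))]
    return "".join(out)


def generate_proteome(n_kinases: int, n_decoys: int,
                      groups: Mapping[str, float] | None = None,
                      mutation_rate: float = 0.15,
                      seed: int = 0) -> ProteomeTruth:
    """Generate a proteome with planted, labeled kinase domains.

    Each kinase protein embeds one point-mutated copy of a group consensus
    domain (group sampled from ``groups``, default uniform over the ten
    groups) inside random flanks of 50-400 residues; decoys are random
    background sequences of comparable length and carry no domain.
    """
    if not 0.0 <= mutation_rate <= 0.4:
        raise ValueError("mutation_rate must lie in [0, 0.4]")
    rng = np.random.default_rng(seed)
    consensi = group_consensi()
    if groups is None:
        groups = {g: 1.0 / len(KINASE_GROUPS) for g in KINASE_GROUPS}
    names = sorted(groups)
    probs = np.array([groups[g] for g in names], dtype=float)
    probs /= probs.sum()

    records: list[ProteinRecord] = []
    truth: list[PlantedDomain] = []
    for i in range(n_kinases):
        group = names[rng.choice(len(names), p=probs)]
        domain = _mutate(rng, consensi[group], mutation_rate)
        left = int(rng.integers(50, 401))
        right = int(rng.integers(50, 401))
        seq = _random_sequence(rng, left) + domain + _random_sequence(rng, right)
        pid = f"KIN{i:05d}"
        records.append(ProteinRecord(pid, seq, f"synthetic {group} kinase"))
        truth.append(PlantedDomain(pid, left, left + len(domain),
                                   group, f"{group}-fam1"))

    decoy_ids: list[str] = []
    for i in range(n_decoys):
        length = int(rng.integers(150, 901))
        pid = f"DEC{i:05d}"
        records.append(ProteinRecord(pid, _random_sequence(rng, length),
                                     "synthetic decoy protein"))
        decoy_ids.append(pid)
    return ProteomeTruth(records=records, truth=truth, decoy_ids=decoy_ids)


def generate_reference_catalog(per_group: int = 3,
                               mutation_rate: float = 0.10,
                               seed: int = 1) -> list[ReferenceKinase]:
    """A labeled catalog of domain sequences derived from the group consensi.

    Entries are independent mutants of each consensus, so they are never
    byte-identical to any planted domain (held out of the proteome
    generator's template draws by their own seed).
    """
    rng = np.random.default_rng(seed)
    consensi = group_consensi()
    catalog: list[ReferenceKinase] = []
    for group in KINASE_GROUPS:
        for i in range(per_group):
            catalog.append(ReferenceKinase(
                id=f"{group}_ref{i + 1}",
                species="synthetic",
                group=group,
                family=f"{group}-fam1",
                subfamily="",
                domain_sequence=_mutate(rng, consensi[group], mutation_rate),
            ))
    return catalog


# ---------------------------------------------------------------------------
# count matrices
# ---------------------------------------------------------------------------

@dataclass
class CountTruth:
    matrix: CountMatrix
    expressed_truth: pd.DataFrame        # gene x stage booleans
    de_truth: pd.DataFrame               # gene x contrast-name directions
    rates: pd.DataFrame                  # underlying Poisson means
    contrasts: list[tuple[str, str]]     # (treatment sample, control sample)
    stage_of: dict[str, str]             # sample -> stage
    stressor_of: dict[tuple[str, str], str]  # contrast -> stressor


def generate_counts(
    n_genes: int = 2000,
    stages: Sequence[str] | None = None,
    stressor_contrasts: Sequence[str] | None = None,
    expressed_fraction: float | Mapping[str, float] | None = None,
    de_fraction: float = 0.10,
    fold_range: tuple[float, float] = (2.0, 8.0),
    library_sizes: Mapping[str, int] | None = None,
    seed: int = 0,
) -> CountTruth:
    """Generate stage and stressor count matrices with known truth.

    Gene lengths are uniform in [500, 5000] bp and baseline expression is
    log-uniform in [2, 200] RPKM for expressed genes; non-expressed genes
    get rates below 0.5 RPKM.  Expression across stages is nested: gene *g*
    is expressed at a stage when its per-gene uniform draw falls below that
    stage's expressed fraction.  Per stressor contrast, a ``de_fraction``
    of control-expressed genes is scaled up or down by a fold drawn from
    ``fold_range`` in the treatment sample.  Counts are Poisson draws from
    the resulting per-sample rates; library sizes vary per sample.
    """
    if not 0.0 <= de_fraction <= 1.0:
        raise ValueError("de_fraction must lie in [0, 1]")
    rng = np.random.default_rng(seed)
    if stages is None and expressed_fraction is None:
        stage_fracs = dict(DEFAULT_STAGE_EXPRESSED_FRACTIONS)
    else:
        if stages is None:
            stages = list(DEFAULT_STAGE_EXPRESSED_FRACTIONS)
        if expressed_fraction is None:
            expressed_fraction = DEFAULT_STAGE_EXPRESSED_FRACTIONS
        if isinstance(expressed_fraction, Mapping):
            stage_fracs = {s: float(expressed_fraction[s]) for s in stages}
        else:
            stage_fracs = {s: float(expressed_fraction) for s in stages}
    if stressor_contrasts is None:
        stressor_contrasts = DEFAULT_STRESSORS
    for frac in stage_fracs.values():
        if not 0.0 <= frac <= 1.0:
            raise ValueError("expressed fractions must lie in [0, 1]")

    genes = [f"G{i:05d}" for i in range(n_genes)]
    lengths = rng.integers(500, 5001, size=n_genes)

    expr_rpkm = 10.0 ** rng.uniform(np.log10(2.0), np.log10(200.0), n_genes)
    silent_rpkm = rng.uniform(0.01, 0.4, n_genes)
    u = rng.random(n_genes)  # per-gene expression propensity (nested across stages)

    samples = list(stage_fracs)
    contrasts: list[tuple[str, str]] = []
    stressor_of: dict[tuple[str, str], str] = {}
    for stressor in stressor_contrasts:
        t, c = f"{stressor}_treated", f"{stressor}_control"
        samples += [t, c]
        contrasts.append((t, c))
        stressor_of[(t, c)] = stressor

    if library_sizes is None:
        libs = {s: int(10.0 ** rng.uniform(6.6, 7.1)) for s in samples}
    else:
        libs = {s: int(library_sizes[s]) for s in samples}

    expressed_truth = pd.DataFrame(
        {s: u < stage_fracs[s] for s in stage_fracs}, index=genes
    )
    adult_expressed = u < ADULT_EXPRESSED_FRACTION

    rates = pd.DataFrame(0.0, index=genes, columns=samples)
    for s in stage_fracs:
        rpkm_s = np.where(expressed_truth[s], expr_rpkm, silent_rpkm)
        rates[s] = rpkm_s * lengths * libs[s] / 1.0e9

    de_truth = pd.DataFrame("none", index=genes,
                            columns=[f"{t}_vs_{c}" for t, c in contrasts])
    for (t, c), name in zip(contrasts, de_truth.columns):
        control_rpkm = np.where(adult_expressed, expr_rpkm, silent_rpkm)
        treated_rpkm = control_rpkm.copy()
        candidates = np.flatnonzero(adult_expressed)
        n_de = int(round(de_fraction * candidates.size))
        chosen = rng.choice(candidates, size=n_de, replace=False)
        for g in chosen:
            fold = rng.uniform(*fold_range)
            if rng.random() < 0.5:
                treated_rpkm[g] = control_rpkm[g] * fold
                de_truth.iloc[g, de_truth.columns.get_loc(name)] = "up"
            else:
                treated_rpkm[g] = control_rpkm[g] / fold
                de_truth.iloc[g, de_truth.columns.get_loc(name)] = "down"
        rates[c] = control_rpkm * lengths * libs[c] / 1.0e9
        rates[t] = treated_rpkm * lengths * libs[t] / 1.0e9

    counts = pd.DataFrame(
        rng.poisson(rates.to_numpy()), index=genes, columns=samples
    )
    matrix = CountMatrix(
        counts=counts,
        gene_lengths=pd.Series(lengths, index=genes),
        library_sizes=pd.Series(libs),
    )
    return CountTruth(
        matrix=matrix,
        expressed_truth=expressed_truth,
        de_truth=de_truth,
        rates=rates,
        contrasts=contrasts,
        stage_of={s: s for s in stage_fracs},
        stressor_of=stressor_of,
    )


# ---------------------------------------------------------------------------
# tabulation fixtures: build catalog/expression/DE objects from given counts
# ---------------------------------------------------------------------------

def catalog_from_group_counts(counts: Mapping[str, int],
                              prefix: str = "CGK") -> list[Classification]:
    """A classification catalog with a prescribed size per group."""
    catalog: list[Classification] = []
    for group in KINASE_GROUPS:
        for i in range(counts.get(group, 0)):
            catalog.append(Classification(
                protein_id=f"{prefix}_{group}_{i:03d}",
                group=group,
                family=f"{group}-fam1",
                status="classified",
            ))
    return catalog


def expressed_fixture_from_stage_counts(
    catalog: Sequence[Classification],
    stage_counts: Mapping[str, Mapping[str, int]],
) -> tuple[pd.DataFrame, dict[str, str]]:
    """A boolean expression matrix realizing prescribed per-group counts.

    ``stage_counts`` maps stage -> {group: number expressed}; each stage is
    realized as one sample in which the first *n* members of each group are
    expressed.  Returns the matrix and the sample->stage mapping.
    """
    by_group: dict[str, list[str]] = {}
    for c in catalog:
        by_group.setdefault(c.group, []).append(c.protein_id)
    genes = [c.protein_id for c in catalog]
    stage_of: dict[str, str] = {}
    data = {}
    for stage, per_group in stage_counts.items():
        sample = f"s_{stage}"
        stage_of[sample] = stage
        expressed = set()
        for group, n in per_group.items():
            members = by_group.get(group, [])
            if n > len(members):
                raise ValueError(
                    f"stage {stage!r}: {n} expressed requested but group "
                    f"{group!r} has only {len(members)} members"
                )
            expressed.update(members[:n])
        data[sample] = [g in expressed for g in genes]
    return pd.DataFrame(data, index=genes), stage_of


def de_fixture_from_updown_counts(
    catalog: Sequence[Classification],
    updown: Mapping[str, Mapping[str, tuple[int, int]]],
) -> tuple[list[DEResult], dict[tuple[str, str], str]]:
    """DE results realizing prescribed per-group up/down counts per stressor.

    ``updown`` maps stressor -> {group: (n_up, n_down)}; the up and down
    gene sets within one stressor are disjoint (the first *n_up* members of
    each group go up, the next *n_down* go down).
    """
    by_group: dict[str, list[str]] = {}
    for c in catalog:
        by_group.setdefault(c.group, []).append(c.protein_id)
    results: list[DEResult] = []
    stressor_of: dict[tuple[str, str], str] = {}
    for stressor, per_group in updown.items():
        contrast = (f"{stressor}_treated", f"{stressor}_control")
        stressor_of[contrast] = stressor
        for group, (n_up, n_down) in per_group.items():
            members = by_group.get(group, [])
            if n_up + n_down > len(members):
                raise ValueError(
                    f"stressor {stressor!r}: group {group!r} has "
                    f"{len(members)} members but {n_up}+{n_down} requested"
                )
            for gene in members[:n_up]:
                results.append(DEResult(gene, contrast, 1e-6, 1e-6, "up", 4.0))
            for gene in members[n_up:n_up + n_down]:
                results.append(DEResult(gene, contrast, 1e-6, 1e-6, "down", 0.25))
    return results, stressor_of
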