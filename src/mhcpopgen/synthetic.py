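"""Seeded generators for every input the pipeline consumes.

Three generators cover the three analysis stages:

* :func:`simulate_multilocus_dataset` emulates a clone-sequencing survey of
  co-amplified duplicated MHC loci: per-locus HWE genotypes (optionally with
  invisible null alleles), pooled per-individual allele sets, clone
  resampling with singleton PCR artifacts, and the ground-truth genotypes
  and partition for recovery scoring. The defaults mirror a two-locus
  survey with 20 sequenced clones per individual.
* :func:`simulate_structured_populations` draws per-population allele
  frequencies from a Balding-Nichols Dirichlet model with a target F_ST and
  HWE genotypes within populations - the test bed for the Weir-Cockerham
  estimators.
* :func:`simulate_codon_alignment` mutates a stop-free reference codon
  sequence independently per row, accepting nonsynonymous changes with
  probability proportional to the omega of the codon's site class - the
  test bed for the Nei-Gojobori statistics.

All generators take an explicit integer seed and are deterministic given it.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io_model import (
    AlleleSequence,
    AlleleSet,
    CloneObservation,
    GenotypeDataset,
    ObservedAlleleSet,
)
from .selection import BASES, STOP_CODONS, CodonAlignment, translate_codon


@dataclass
class SimConfig:
    """Study design for the duplicated-locus clone-sequencing simulator."""

    m: int = 2
    alleles_per_locus: list[int] = field(default_factory=lambda: [6, 4])
    freqs: list[list[float]] | None = None  # None: symmetric Dirichlet(1)
    n_individuals: int = 100
    null_rate: list[float] | float = 0.0
    clone_count: int = 20
    pcr_count: int = 3
    artifact_rate: float = 0.0
    seq_length: int = 60
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.alleles_per_locus) != self.m:
            raise ValueError("alleles_per_locus must have one entry per locus")
        if isinstance(self.null_rate, (int, float)):
            self.null_rate = [float(self.null_rate)] * self.m
        if len(self.null_rate) != self.m:
            raise ValueError("null_rate must have one entry per locus")
        for r in list(self.null_rate) + [self.artifact_rate]:
            if not 0 <= r <= 1:
                raise ValueError("rates must be in [0, 1]")
        if self.freqs is not None:
            if len(self.freqs) != self.m:
                raise ValueError("freqs must have one vector per locus")
            for l, f in enumerate(self.freqs):
                if len(f) != self.alleles_per_locus[l]:
                    raise ValueError("freqs length mismatch")
                if abs(sum(f) - 1) > 1e-9:
                    raise ValueError("per-locus frequencies must sum to 1")


@dataclass
class MultilocusTruth:
    genotypes: GenotypeDataset
    partition: dict[str, int]
    freqs: list[dict[str, float]]
    alleles: AlleleSet
    observed_sets: list[ObservedAlleleSet]
    flagged_all_null: list[str]


def _random_sequences(rng: np.random.Generator, n: int, length: int) -> list[str]:
    """Distinct random nucleotide sequences (no stop-free guarantee)."""
    out: set[str] = set()
    while len(out) < n:
        out.add("".join(rng.choice(list(BASES), size=length)))
    return sorted(out)


def simulate_multilocus_dataset(
    cfg: SimConfig,
) -> tuple[list[CloneObservation], MultilocusTruth]:
    """Simulate a clone-sequencing survey of m co-amplified loci under HWE.

    Per individual and locus a diploid genotype is drawn from the locus
    frequencies (a null allele at ``null_rate`` is invisible in
    observations); the observed set is the union of non-null alleles;
    ``clone_count`` clones are drawn uniformly from the observed set, each
    independently replaced by a unique singleton artifact sequence with
    probability ``artifact_rate``. Ground truth (genotypes, partition,
    frequencies) is returned for recovery scoring.
    """
    rng = np.random.default_rng(cfg.seed)
    # allele panel: disjoint pools, one shared amplicon length
    names: list[str] = []
    partition: dict[str, int] = {}
    for l in range(cfg.m):
        for i in range(cfg.alleles_per_locus[l]):
            nm = f"L{l + 1}A{i + 1:02d}"
            names.append(nm)
            partition[nm] = l + 1
    seqs = _random_sequences(rng, len(names), cfg.seq_length)
    panel = AlleleSet(
        [AlleleSequence(name=nm, nt_seq=sq) for nm, sq in zip(names, seqs)]
    )

    freqs: list[dict[str, float]] = []
    for l in range(cfg.m):
        held = [nm for nm in names if partition[nm] == l + 1]
        if cfg.freqs is not None:
            base = np.asarray(cfg.freqs[l], dtype=float)
        else:
            base = rng.dirichlet(np.ones(len(held)))
        null = cfg.null_rate[l]
        vec = {nm: float(p * (1 - null)) for nm, p in zip(held, base)}
        if null > 0:
            vec["<null>"] = null
        freqs.append(vec)

    rows = []
    clones: list[CloneObservation] = []
    observed_sets: list[ObservedAlleleSet] = []
    flagged: list[str] = []
    artifact_counter = itertools.count(1)
    for ind in range(cfg.n_individuals):
        ind_id = f"ind{ind + 1:04d}"
        observed: set[str] = set()
        for l in range(cfg.m):
            held = sorted(freqs[l])
            p = np.array([freqs[l][a] for a in held])
            ia, ib = rng.choice(len(held), size=2, p=p / p.sum())
            a, b = held[ia], held[ib]
            ga, gb = sorted((a, b))
            rows.append(
                {
                    "individual_id": ind_id,
                    "population": "sim",
                    "locus": f"locus{l + 1}",
                    "allele_a": "." if ga == "<null>" else ga,
                    "allele_b": "." if gb == "<null>" else gb,
                }
            )
            observed.update(x for x in (a, b) if x != "<null>")
        if not observed:
            flagged.append(ind_id)
        else:
            observed_sets.append(
                ObservedAlleleSet(
                    individual_id=ind_id, population="sim", alleles=frozenset(observed)
                )
            )
        obs_sorted = sorted(observed)
        for c in range(cfg.clone_count):
            pcr = f"pcr{(c % cfg.pcr_count) + 1}"
            if obs_sorted and rng.random() >= cfg.artifact_rate:
                seq = panel[obs_sorted[int(rng.integers(0, len(obs_sorted)))]].nt_seq
            else:
                # singleton artifact: unique sequence absent from the panel
                seq = _mutate_unique(
                    rng, seqs, cfg.seq_length, next(artifact_counter)
                )
            clones.append(
                CloneObservation(
                    individual_id=ind_id,
                    population="sim",
                    pcr_id=pcr,
                    clone_id=f"clone{c + 1:02d}",
                    nt_seq=seq,
                )
            )
    truth = MultilocusTruth(
        genotypes=GenotypeDataset(pd.DataFrame(rows)),
        partition=partition,
        freqs=freqs,
        alleles=panel,
        observed_sets=observed_sets,
        flagged_all_null=flagged,
    )
    return clones, truth


def _mutate_unique(rng, panel_seqs, length, counter) -> str:
    while True:
        s = "".join(rng.choice(list(BASES), size=length))
        if s not in panel_seqs:
            return s


def simulate_structured_populations(
    n_pops: int,
    fst_target: float,
    base_freqs: dict[str, float],
    n_per_pop: int,
    seed: int,
    n_loci: int = 1,
    locus_prefix: str = "locus",
) -> GenotypeDataset:
    """HWE genotypes in ``n_pops`` populations differentiated at a target F_ST.

    Population frequencies follow the Balding-Nichols model: Dirichlet with
    concentration ``p * (1 - F)/F`` around the base frequencies, under which
    E[F_ST] = ``fst_target``; ``fst_target=0`` copies the base frequencies.
    """
    if not 0 <= fst_target < 1:
        raise ValueError("fst_target must be in [0, 1)")
    if n_pops < 2:
        raise ValueError("need at least two populations")
    base = np.asarray(list(base_freqs.values()), dtype=float)
    names = list(base_freqs)
    if len(names) < 2 or (base <= 0).any() or abs(base.sum() - 1) > 1e-9:
        raise ValueError("base_freqs must be >= 2 positive frequencies summing to 1")
    rng = np.random.default_rng(seed)
    rows = []
    for locus in range(n_loci):
        for pop in range(n_pops):
            if fst_target == 0:
                p = base
            else:
                conc = base * (1 - fst_target) / fst_target
                p = rng.dirichlet(conc)
            for ind in range(n_per_pop):
                ia, ib = rng.choice(len(names), size=2, p=p)
                ga, gb = sorted((names[ia], names[ib]))
                rows.append(
                    {
                        "individual_id": f"p{pop + 1}i{ind + 1:04d}",
                        "population": f"pop{pop + 1}",
                        "locus": f"{locus_prefix}{locus + 1}",
                        "allele_a": ga,
                        "allele_b": gb,
                    }
                )
    return GenotypeDataset(pd.DataFrame(rows))


def random_reference(rng: np.random.Generator, n_codons: int) -> str:
    """Random stop-free in-frame reference sequence."""
    codons = []
    sense = sorted(set(_all_codons()) - STOP_CODONS)
    for _ in range(n_codons):
        codons.append(sense[int(rng.integers(0, len(sense)))])
    return "".join(codons)


def _all_codons():
    return ["".join(c) for c in itertools.product(BASES, repeat=3)]


def simulate_codon_alignment(
    n_seqs: int,
    n_codons: int,
    mask: dict[int, str] | None,
    omega_by_class: dict[str, float],
    subs_per_seq: int,
    seed: int,
) -> CodonAlignment:
    """Star-genealogy codon alignment with site-class-specific selection.

    Each row mutates an identical stop-free reference independently:
    ``subs_per_seq`` candidate single-base changes are proposed uniformly;
    a synonymous candidate is always accepted, a nonsynonymous one with
    probability ``omega / max(1, max omega)`` for the codon's class; changes
    creating stop codons are rejected outright.
    """
    if n_codons < 2:
        raise ValueError("need at least 2 codons")
    for w in omega_by_class.values():
        if w <= 0:
            raise ValueError("omega values must be > 0")
    if mask is None:
        mask = {i: "all" for i in range(1, n_codons + 1)}
        if set(omega_by_class) != {"all"}:
            raise ValueError("without a mask, omega_by_class must be keyed 'all'")
    missing = [i for i in range(1, n_codons + 1) if i not in mask]
    if missing:
        raise ValueError(f"mask does not cover codons {missing[:5]}")
    rng = np.random.default_rng(seed)
    ref = random_reference(rng, n_codons)
    wmax = max(1.0, max(omega_by_class.values()))
    rows = []
    for s in range(n_seqs):
        seq = list(ref)
        for _ in range(subs_per_seq):
            pos = int(rng.integers(0, 3 * n_codons))
            codon_i = pos // 3
            old_codon = "".join(seq[3 * codon_i : 3 * codon_i + 3])
            b = BASES[int(rng.integers(0, 4))]
            if b == seq[pos]:
                continue
            new_codon = (
                old_codon[: pos % 3] + b + old_codon[pos % 3 + 1 :]
            )
            if new_codon in STOP_CODONS:
                continue
            # relative acceptance: omega for nonsynonymous, 1 for synonymous,
            # both scaled by 1/max so rates stay proportional across classes
            if translate_codon(new_codon) == translate_codon(old_codon):
                w = 1.0
            else:
                w = omega_by_class[mask[codon_i + 1]]
            if rng.random() < w / wmax:
                seq[pos] = b
        rows.append("".join(seq))
    return CodonAlignment(names=[f"seq{i + 1:02d}" for i in range(n_seqs)], sequences=rows)


def synthetic_drb_panel(
    n_alleles: int = 19,
    seed: int = 20180313,
    intron_len: int = 23,
    exon_len: int = 247,
    abs_codons: list[int] | None = None,
) -> AlleleSet:
    """SYNTHETIC stand-in for a published DRB exon-2 allele panel.

    Builds a panel of ``n_alleles`` amplicon sequences (intron-1 stub +
    exon 2, frame offset 2, 81 complete codons) with elevated nonsynonymous
    diversity at the ABS codons and one allele carrying a 3-bp in-frame
    deletion, mimicking the qualitative structure of real DRB exon-2 panels.
    It is generated data, not the published sequences, and is only suitable
    for exercising the pipeline, never for reproducing published estimates.
    """
    rng = np.random.default_rng(seed)
    frame_offset = 2
    n_codons = (exon_len - frame_offset) // 3
    if abs_codons is None:
        abs_codons = [4, 6, 8, 23, 25, 27, 32, 33, 42, 51, 52, 55, 56, 62, 65, 66, 69, 73]
    mask = {
        i: ("ABS" if i in set(abs_codons) else "non-ABS")
        for i in range(1, n_codons + 1)
    }
    aln = simulate_codon_alignment(
        n_seqs=n_alleles,
        n_codons=n_codons,
        mask=mask,
        omega_by_class={"ABS": 5.0, "non-ABS": 0.3},
        subs_per_seq=30,
        seed=int(rng.integers(0, 2**31 - 1)),
    )
    intron = "".join(rng.choice(list(BASES), size=intron_len))
    lead = "".join(rng.choice(list(BASES), size=frame_offset))
    tail_len = exon_len - frame_offset - 3 * n_codons
    tail = "".join(rng.choice(list(BASES), size=tail_len))
    alleles = []
    for i, coding in enumerate(aln.sequences):
        name = f"Synth-DRB*{i + 1:02d}"
        nt = intron + lead + coding + tail
        alleles.append(
            AlleleSequence(
                name=name,
                nt_seq=nt,
                frame_offset=frame_offset,
                exon_len=exon_len,
                intron_len=intron_len,
            )
        )
    # one allele with a 3-bp in-frame deletion, gapped against the amplicon
    victim = alleles[-1]
    cut = intron_len + frame_offset + 3 * 10  # delete codon 11
    victim.nt_seq = victim.nt_seq[:cut] + "---" + victim.nt_seq[cut + 3 :]
    return AlleleSet(alleles)
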