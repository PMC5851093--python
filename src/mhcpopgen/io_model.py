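"""Domain types and file I/O for MHC allele panels, clone tables and genotypes.

The central objects are :class:`AlleleSequence` (a named exon-2 nucleotide
sequence, possibly gapped against the amplicon coordinate frame when it
carries an in-frame deletion), :class:`AlleleSet` (an ordered, name-unique
collection of alleles), :class:`CloneObservation` (one sequenced clone of one
PCR of one individual) and :class:`ObservedAlleleSet` (the deduplicated,
locus-unresolved allele set of one individual).

Allele validation follows the standard clone-sequencing artifact rule for MHC
surveys of duplicated loci: a distinct sequence is accepted as a real allele
only if it was seen in at least ``min_individuals`` different individuals, or
in at least ``min_pcrs`` independent PCRs of a single individual, or if it
exactly matches a previously published allele.
"""

from __future__ import annotations

import logging
import re
from collections import defaultdict
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

logger = logging.getLogger(__name__)

MISSING = "."

_VALID_CHARS = set("ACGTN-")


class FormatError(ValueError):
    """Raised for malformed input files or sequences."""


@dataclass
class AlleleSequence:
    """A named allele sequence in amplicon coordinates.

    Parameters
    ----------
    name:
        Allele identifier, e.g. ``"Rhro-DRB*03"``.
    nt_seq:
        Nucleotide sequence over ``{A,C,G,T,N,-}``; gap characters are only
        legal for alleles carrying an in-frame deletion (gap run length
        divisible by 3).
    frame_offset:
        Bases of the exon region to skip before the first complete codon.
    exon_len, intron_len:
        Lengths (bp) of the exon-2 and intron-1 parts of the amplicon. The
        intron, when present, precedes the exon. ``exon_len`` of 0 means the
        whole sequence is treated as exon.
    """

    name: str
    nt_seq: str
    frame_offset: int = 0
    exon_len: int = 0
    intron_len: int = 0

    def __post_init__(self) -> None:
        self.nt_seq = self.nt_seq.upper()
        if not self.nt_seq:
            raise FormatError(f"allele {self.name!r}: empty sequence")
        if self.frame_offset not in (0, 1, 2):
            raise ValueError(f"allele {self.name!r}: frame_offset must be 0, 1 or 2")
        for i, c in enumerate(self.nt_seq):
            if c not in _VALID_CHARS:
                raise FormatError(
                    f"allele {self.name!r}: illegal character {c!r} at position {i + 1}"
                )
        for run in re.finditer(r"-+", self.nt_seq):
            if len(run.group()) % 3 != 0:
                # tolerated at construction; flagged as frameshift on translation
                logger.debug(
                    "allele %s: gap run of length %d not divisible by 3",
                    self.name,
                    len(run.group()),
                )

    @property
    def exon_seq(self) -> str:
        """The exon part of the sequence (amplicon minus leading intron)."""
        if self.exon_len:
            return self.nt_seq[self.intron_len : self.intron_len + self.exon_len]
        return self.nt_seq[self.intron_len :] if self.intron_len else self.nt_seq

    def ungapped(self) -> str:
        return self.nt_seq.replace("-", "")


class AlleleSet:
    """Ordered collection of :class:`AlleleSequence` with unique names."""

    def __init__(self, alleles: list[AlleleSequence] | None = None):
        self._alleles: dict[str, AlleleSequence] = {}
        for a in alleles or []:
            self.add(a)

    def add(self, allele: AlleleSequence) -> None:
        if allele.name in self._alleles:
            raise FormatError(f"duplicate allele name {allele.name!r}")
        self._alleles[allele.name] = allele

    def __len__(self) -> int:
        return len(self._alleles)

    def __iter__(self):
        return iter(self._alleles.values())

    def __contains__(self, name: str) -> bool:
        return name in self._alleles

    def __getitem__(self, name: str) -> AlleleSequence:
        return self._alleles[name]

    @property
    def names(self) -> list[str]:
        return list(self._alleles)

    def by_sequence(self) -> dict[str, str]:
        """Mapping from uppercased, gap-normalized sequence to allele name."""
        return {normalize_sequence(a.nt_seq): a.name for a in self}


def normalize_sequence(seq: str) -> str:
    """Uppercase and strip alignment gaps; the unit of sequence identity."""
    return seq.upper().replace("-", "")


@dataclass(frozen=True)
class CloneObservation:
    individual_id: str
    population: str
    pcr_id: str
    clone_id: str
    nt_seq: str

    def __post_init__(self) -> None:
        if not self.nt_seq:
            raise FormatError(
                f"clone {self.individual_id}/{self.pcr_id}/{self.clone_id}: empty sequence"
            )


@dataclass
class AlleleSupport:
    """Evidence behind one accepted allele."""

    n_individuals: int
    n_pcrs_max_one_individual: int
    matched_known: bool


@dataclass
class ObservedAlleleSet:
    """One individual's deduplicated, locus-unresolved allele observations."""

    individual_id: str
    population: str
    alleles: frozenset[str]
    support: dict[str, AlleleSupport] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if isinstance(self.alleles, (list, set, tuple)):
            self.alleles = frozenset(self.alleles)


class GenotypeDataset:
    """Per-locus diploid genotypes as a tidy table.

    Columns: ``individual_id, population, locus, allele_a, allele_b``;
    missing alleles are coded ``"."``. Each (individual, locus) pair appears
    at most once.
    """

    COLUMNS = ["individual_id", "population", "locus", "allele_a", "allele_b"]

    def __init__(self, df: pd.DataFrame):
        missing_cols = set(self.COLUMNS) - set(df.columns)
        if missing_cols:
            raise FormatError(f"genotype table missing columns {sorted(missing_cols)}")
        df = df[self.COLUMNS].astype(str).reset_index(drop=True)
        dup = df.duplicated(subset=["individual_id", "locus"])
        if dup.any():
            raise FormatError("duplicate (individual, locus) rows in genotype table")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    @property
    def loci(self) -> list[str]:
        return sorted(self.df["locus"].unique())

    @property
    def populations(self) -> list[str]:
        return sorted(self.df["population"].unique())

    def called(self) -> pd.DataFrame:
        """Rows with both alleles called."""
        m = (self.df["allele_a"] != MISSING) & (self.df["allele_b"] != MISSING)
        return self.df[m]


@dataclass
class SiteMask:
    """Per-codon functional classes over an in-frame alignment.

    ``codon_class`` maps 1-based codon index to ``"ABS"`` or ``"non-ABS"``.
    """

    codon_class: dict[int, str]

    def indices(self, site_class: str) -> list[int]:
        return sorted(i for i, c in self.codon_class.items() if c == site_class)

    def validate_against(self, codon_count: int) -> None:
        missing = [i for i in range(1, codon_count + 1) if i not in self.codon_class]
        if missing:
            raise FormatError(f"mask missing codon classes for codons {missing[:5]}...")


# ---------------------------------------------------------------------------
# File I/O


def read_allele_fasta(path) -> AlleleSet:
    """Read an allele panel from FASTA, preserving record order.

    Raises :class:`FormatError` on duplicate headers or illegal characters.
    An empty file yields an empty :class:`AlleleSet` with a warning.
    """
    alleles = AlleleSet()
    n = 0
    for rec in SeqIO.parse(str(path), "fasta"):
        n += 1
        alleles.add(AlleleSequence(name=rec.id, nt_seq=str(rec.seq)))
    if n == 0:
        logger.warning("no FASTA records found in %s", path)
    return alleles


def write_allele_fasta(alleles: AlleleSet, path) -> None:
    with open(path, "w") as fh:
        for a in alleles:
            fh.write(f">{a.name}\n{a.nt_seq}\n")


def read_clone_table(path) -> list[CloneObservation]:
    """Read a clone-sequencing table.

    CSV header: ``individual_id,population,pcr_id,clone_id,sequence``.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["individual_id", "population", "pcr_id", "clone_id", "sequence"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"clone table missing columns {sorted(missing)}")
    seen = set()
    clones = []
    for row in df.itertuples(index=False):
        key = (row.individual_id, row.pcr_id, row.clone_id)
        if key in seen:
            raise FormatError(f"duplicate clone key {key}")
        seen.add(key)
        clones.append(
            CloneObservation(
                individual_id=row.individual_id,
                population=row.population,
                pcr_id=row.pcr_id,
                clone_id=row.clone_id,
                nt_seq=str(row.sequence).upper(),
            )
        )
    return clones


def write_clone_table(clones: list[CloneObservation], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": c.individual_id,
                "population": c.population,
                "pcr_id": c.pcr_id,
                "clone_id": c.clone_id,
                "sequence": c.nt_seq,
            }
            for c in clones
        ]
    ).to_csv(path, index=False)


def read_observed_sets(path) -> list[ObservedAlleleSet]:
    """Read per-individual observed allele sets.

    CSV header ``individual_id,population,alleles``, alleles
    semicolon-delimited.
    """
    df = pd.read_csv(path, dtype=str)
    required = ["individual_id", "population", "alleles"]
    missing = set(required) - set(df.columns)
    if missing:
        raise FormatError(f"observed-set table missing columns {sorted(missing)}")
    out = []
    for row in df.itertuples(index=False):
        names = frozenset(a for a in str(row.alleles).split(";") if a)
        if not names:
            raise FormatError(f"individual {row.individual_id}: empty allele set")
        out.append(
            ObservedAlleleSet(
                individual_id=row.individual_id,
                population=row.population,
                alleles=names,
            )
        )
    return out


def write_observed_sets(sets: list[ObservedAlleleSet], path) -> None:
    pd.DataFrame(
        [
            {
                "individual_id": s.individual_id,
                "population": s.population,
                "alleles": ";".join(sorted(s.alleles)),
            }
            for s in sets
        ]
    ).to_csv(path, index=False)


def read_genotypes(path) -> GenotypeDataset:
    return GenotypeDataset(pd.read_csv(path, dtype=str))


def write_genotypes(ds: GenotypeDataset, path) -> None:
    ds.df.to_csv(path, index=False)


def read_site_mask(path) -> SiteMask:
    """Read a codon-class mask (CSV ``codon_index,class``)."""
    df = pd.read_csv(path, comment="#")
    if "codon_index" not in df.columns or "class" not in df.columns:
        raise FormatError("mask file needs columns codon_index,class")
    mapping = {}
    for _, row in df.iterrows():
        idx = int(row["codon_index"])
        cls = str(row["class"]).strip()
        if idx in mapping:
            raise FormatError(f"mask lists codon {idx} twice")
        if cls not in ("ABS", "non-ABS"):
            raise FormatError(f"mask class must be ABS or non-ABS, got {cls!r}")
        mapping[idx] = cls
    return SiteMask(codon_class=mapping)


# ---------------------------------------------------------------------------
# Allele validation


_SUFFIX_RE = re.compile(r"^(?P<prefix>.*?)(?P<num>\d+)$")


def _new_allele_name(known_names: list[str], offset: int) -> str:
    """Next allele name per the numeric-suffix nomenclature.

    Numbering continues from the highest numeric suffix among known names;
    the most common prefix among suffixed names is reused. Without any
    suffixed known name, names are ``novel*<n>`` starting at 1.
    """
    best_num = 0
    prefixes: dict[str, int] = defaultdict(int)
    width = 2
    for name in known_names:
        m = _SUFFIX_RE.match(name)
        if m:
            num = int(m.group("num"))
            prefixes[m.group("prefix")] += 1
            if num > best_num:
                best_num = num
                width = len(m.group("num"))
    prefix = max(prefixes, key=prefixes.get) if prefixes else "novel*"
    return f"{prefix}{best_num + 1 + offset:0{width}d}"


@dataclass
class RejectedSequence:
    nt_seq: str
    n_individuals: int
    n_pcrs_max_one_individual: int
    reason: str


@dataclass
class ValidationResult:
    accepted: AlleleSet
    observed_sets: list[ObservedAlleleSet]
    rejected: list[RejectedSequence]
    excluded_individuals: list[str]


def validate_alleles(
    clones: list[CloneObservation],
    known: AlleleSet,
    min_individuals: int = 2,
    min_pcrs: int = 3,
) -> ValidationResult:
    """Screen clone sequences into validated alleles and per-individual sets.

    A distinct sequence (exact identity after uppercasing and gap removal)
    is accepted iff it was seen in ``>= min_individuals`` individuals, or in
    ``>= min_pcrs`` distinct PCRs of one individual, or it matches a
    sequence in ``known``. Accepted novel sequences are named by continuing
    the numeric-suffix series of the known panel, in order of discovery
    (first appearance in the input after sorting by sequence for
    determinism).
    """
    known_by_seq = known.by_sequence()

    by_seq_individuals: dict[str, set[str]] = defaultdict(set)
    by_seq_pcrs: dict[str, dict[str, set[str]]] = defaultdict(lambda: defaultdict(set))
    for c in clones:
        key = normalize_sequence(c.nt_seq)
        by_seq_individuals[key].add(c.individual_id)
        by_seq_pcrs[key][c.individual_id].add(c.pcr_id)

    accepted = AlleleSet()
    seq_to_name: dict[str, str] = {}
    rejected: list[RejectedSequence] = []
    novel_offset = 0
    # deterministic order independent of clone-row order
    for key in sorted(by_seq_individuals):
        n_ind = len(by_seq_individuals[key])
        max_pcrs = max(len(p) for p in by_seq_pcrs[key].values())
        matched = key in known_by_seq
        if matched or n_ind >= min_individuals or max_pcrs >= min_pcrs:
            if matched:
                name = known_by_seq[key]
                template = known[name]
                allele = AlleleSequence(
                    name=name,
                    nt_seq=template.nt_seq,
                    frame_offset=template.frame_offset,
                    exon_len=template.exon_len,
                    intron_len=template.intron_len,
                )
            else:
                name = _new_allele_name(known.names, novel_offset)
                novel_offset += 1
                allele = AlleleSequence(name=name, nt_seq=key)
            accepted.add(allele)
            seq_to_name[key] = name
        else:
            rejected.append(
                RejectedSequence(
                    nt_seq=key,
                    n_individuals=n_ind,
                    n_pcrs_max_one_individual=max_pcrs,
                    reason=(
                        f"putative PCR artifact: seen in {n_ind} individual(s) "
                        f"and at most {max_pcrs} PCR(s) of one individual"
                    ),
                )
            )

    per_ind: dict[str, set[str]] = defaultdict(set)
    pops: dict[str, str] = {}
    order: list[str] = []
    for c in clones:
        if c.individual_id not in pops:
            order.append(c.individual_id)
        pops[c.individual_id] = c.population
        key = normalize_sequence(c.nt_seq)
        if key in seq_to_name:
            per_ind[c.individual_id].add(seq_to_name[key])

    observed_sets: list[ObservedAlleleSet] = []
    excluded: list[str] = []
    for ind in order:
        names = per_ind.get(ind, set())
        if not names:
            logger.warning("individual %s has no accepted alleles; excluded", ind)
            excluded.append(ind)
            continue
        support = {}
        for nm in names:
            key = next(k for k, v in seq_to_name.items() if v == nm)
            support[nm] = AlleleSupport(
                n_individuals=len(by_seq_individuals[key]),
                n_pcrs_max_one_individual=max(
                    len(p) for p in by_seq_pcrs[key].values()
                ),
                matched_known=key in known_by_seq,
            )
        observed_sets.append(
            ObservedAlleleSet(
                individual_id=ind,
                population=pops[ind],
                alleles=frozenset(names),
                support=support,
            )
        )
    return ValidationResult(
        accepted=accepted,
        observed_sets=observed_sets,
        rejected=rejected,
        excluded_individuals=excluded,
    )


# ---------------------------------------------------------------------------
# Translation screening


@dataclass
class TranslationFlags:
    has_stop: bool
    has_frameshift: bool
    has_inframe_indel: bool

    @property
    def functional(self) -> bool:
        return not (self.has_stop or self.has_frameshift)


def translate_and_screen(allele: AlleleSequence) -> tuple[str, TranslationFlags]:
    """Translate the exon region and flag pseudogene signatures.

    Translation covers the complete codons of the gap-stripped exon after
    skipping ``frame_offset`` leading bases. Flags: ``has_stop`` (internal or
    terminal stop), ``has_frameshift`` (any gap run whose length is not a
    multiple of 3), ``has_inframe_indel`` (gap runs of length divisible
    by 3). Ambiguous bases translate to ``X``.
    """
    exon = allele.exon_seq
    has_frameshift = False
    has_indel = False
    for run in re.finditer(r"-+", exon):
        if len(run.group()) % 3 == 0:
            has_indel = True
        else:
            has_frameshift = True
    coding = exon.replace("-", "")[allele.frame_offset :]
    coding = coding[: len(coding) - len(coding) % 3]
    protein = str(Seq(coding).translate()) if coding else ""
    flags = TranslationFlags(
        has_stop="*" in protein,
        has_frameshift=has_frameshift,
        has_inframe_indel=has_indel,
    )
    return protein, flags
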