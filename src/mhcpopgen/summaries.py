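"""Pipeline-level summary tables.

Reproduces the conventional per-population diversity summary from a printed
allele-frequency table: integer allele counts are reconstructed from the
rounded frequencies by largest-remainder rounding, per-population statistics
are computed from those counts, and pooled ("All") rows follow the mixed
convention of the standard toolchain - H_E and PIC from counts pooled over
individuals, A_E as the arithmetic mean across populations.
"""

from __future__ import annotations

from importlib import resources

import pandas as pd

from .popgen import (
    AlleleCountTable,
    allelic_richness,
    counts_from_frequencies,
    effective_allele_number,
    pic,
    pool_counts,
    unbiased_expected_heterozygosity,
)


def bundled_path(name: str):
    """Path to a bundled data file (context manager not needed: real files)."""
    return resources.files("mhcpopgen.data") / name


def read_frequency_table(path) -> pd.DataFrame:
    df = pd.read_csv(path, comment="#")
    required = {"population", "locus", "allele", "frequency", "n_individuals"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"frequency table missing columns {sorted(missing)}")
    return df


def counts_from_table(df: pd.DataFrame) -> list[AlleleCountTable]:
    """Reconstruct per population x locus count tables from frequencies."""
    tables = []
    for (pop, locus), grp in df.groupby(["population", "locus"], sort=True):
        n = int(grp["n_individuals"].iloc[0])
        freqs = dict(zip(grp["allele"], grp["frequency"].astype(float)))
        tables.append(
            counts_from_frequencies(freqs, n, population=pop, locus=locus)
        )
    return tables


def diversity_summary(
    tables: list[AlleleCountTable],
    rarefaction_g: int | None = None,
    pooled_label: str = "All",
) -> pd.DataFrame:
    """Per-population rows plus a pooled row per locus.

    The pooled row's H_E/PIC/A_R come from summed counts; its A_E is the
    mean of the per-population values. ``rarefaction_g`` defaults to the
    minimum gene count over per-population tables.
    """
    if rarefaction_g is None:
        rarefaction_g = min(t.gene_count for t in tables)
    rows = []
    by_locus: dict[str, list[AlleleCountTable]] = {}
    for t in tables:
        by_locus.setdefault(t.locus, []).append(t)
    for locus in sorted(by_locus):
        per_pop_ae = []
        for t in sorted(by_locus[locus], key=lambda t: t.population):
            ae = effective_allele_number(t)
            per_pop_ae.append(ae)
            rows.append(
                {
                    "population": t.population,
                    "locus": locus,
                    "n": t.n_individuals,
                    "k": t.k,
                    "h_exp": unbiased_expected_heterozygosity(t),
                    "pic": pic(t),
                    "a_e": ae,
                    "a_r": allelic_richness(t, rarefaction_g)
                    if rarefaction_g <= t.gene_count
                    else float("nan"),
                }
            )
        pooled = pool_counts(by_locus[locus], population=pooled_label)
        rows.append(
            {
                "population": pooled_label,
                "locus": locus,
                "n": pooled.n_individuals,
                "k": pooled.k,
                "h_exp": unbiased_expected_heterozygosity(pooled),
                "pic": pic(pooled),
                "a_e": sum(per_pop_ae) / len(per_pop_ae),
                "a_r": allelic_richness(pooled, rarefaction_g),
            }
        )
    return pd.DataFrame(rows)
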