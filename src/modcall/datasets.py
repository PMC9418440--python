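"""Programmatic construction of small worked-example datasets.

These builders assemble site catalogs, read-count tables and DE tables
with exactly specified summary structure (so the report operations can
be exercised on published-scale inputs without any real data).  All
outputs are deterministic.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .models import ModSite

#: spacing between synthetic sites on one transcript, comfortably larger
#: than the collapse window so matching is unambiguous
_SPACING = 100


def _make_site(
    site_id: str,
    transcript_id: str,
    start: int,
    rate_stress: float = 0.5,
    rate_control: float = 0.25,
) -> ModSite:
    return ModSite(
        site_id=site_id,
        transcript_id=transcript_id,
        start=start,
        end=start + 5,
        n_xpore=1,
        n_nanocompore=1,
        best_p_xpore=1e-4,
        best_p_nanocompore=1e-4,
        rate_stress=rate_stress,
        rate_control=rate_control,
        kmer="GGACU",
    )


def _spread(n_sites: int, n_genes: int) -> list[int]:
    """Distribute ``n_sites`` over ``n_genes`` as evenly as possible."""
    if n_genes <= 0 or n_sites < n_genes:
        raise ValueError("need n_sites >= n_genes >= 1")
    base, extra = divmod(n_sites, n_genes)
    return [base + (1 if i < extra else 0) for i in range(n_genes)]


def sites_over_genes(
    n_sites: int,
    n_genes: int,
    prefix: str = "g",
    rate_stress: float = 0.5,
    rate_control: float = 0.25,
) -> tuple[list[ModSite], dict[str, str]]:
    """Sites spread over genes (one transcript per gene), plus gene map."""
    sites: list[ModSite] = []
    gene_map: dict[str, str] = {}
    if n_sites == 0:
        return sites, gene_map
    k = 0
    for gi, count in enumerate(_spread(n_sites, n_genes)):
        tid = f"{prefix}_tx{gi:05d}"
        gene_map[tid] = f"{prefix}_gene{gi:05d}"
        for ci in range(count):
            sites.append(
                _make_site(
                    f"{prefix}_site{k:05d}",
                    tid,
                    _SPACING * (ci + 1),
                    rate_stress,
                    rate_control,
                )
            )
            k += 1
    return sites, gene_map


def shared_site_catalog(
    n_shared: int,
    n_shared_genes: int,
    n_male_total: int,
    n_female_total: int,
) -> tuple[list[ModSite], list[ModSite], dict[str, str]]:
    """Two sex-specific catalogs sharing an exact number of sites/genes.

    The shared sites occupy identical coordinates in both catalogs;
    each catalog is padded with sites on its own private transcripts up
    to the requested totals.
    """
    shared, gene_map = sites_over_genes(n_shared, n_shared_genes, prefix="sh")
    male_extra, gm = sites_over_genes(
        n_male_total - n_shared, max(n_male_total - n_shared, 1), prefix="m"
    )
    gene_map.update(gm)
    female_extra, gf = sites_over_genes(
        n_female_total - n_shared, max(n_female_total - n_shared, 1), prefix="f"
    )
    gene_map.update(gf)
    return shared + male_extra, shared + female_extra, gene_map


def catalog_with_de(
    n_sites: int,
    n_sites_in_de: int,
    n_de_genes: int,
    n_other_genes: int,
) -> tuple[list[ModSite], pd.DataFrame, dict[str, str]]:
    """A site catalog plus DE table placing an exact site count in DE genes.

    DE genes get fold_change 1.5 and FDR 0.01 (clearly significant);
    all other genes get fold_change 1.05 and FDR 0.5.
    """
    de_sites, gene_map = sites_over_genes(n_sites_in_de, n_de_genes, prefix="de")
    other, gm = sites_over_genes(
        n_sites - n_sites_in_de, n_other_genes, prefix="bg"
    )
    gene_map.update(gm)
    de_genes = sorted({gene_map[s.transcript_id] for s in de_sites})
    other_genes = sorted({gene_map[s.transcript_id] for s in other})
    de = pd.DataFrame(
        [{"gene_id": g, "fold_change": 1.5, "fdr": 0.01} for g in de_genes]
        + [{"gene_id": g, "fold_change": 1.05, "fdr": 0.5} for g in other_genes]
    )
    return de_sites + other, de, gene_map


def counts_catalog(n_total: int, n_eligible: int) -> pd.Series:
    """Read-count table with an exact number of eligible transcripts."""
    if not 0 <= n_eligible <= n_total:
        raise ValueError("need 0 <= n_eligible <= n_total")
    values = np.where(np.arange(n_total) < n_eligible, 100.0, 3.0)
    return pd.Series(
        values,
        index=[f"tx{i:06d}" for i in range(n_total)],
        name="avg_read_count",
    )


def sites_with_rates(
    n: int, rate_stress: float, rate_control: float, prefix: str = "r"
) -> list[ModSite]:
    """Sites whose representative rates all equal the given means."""
    sites, _ = sites_over_genes(
        n, n, prefix=prefix, rate_stress=rate_stress, rate_control=rate_control
    )
    return sites
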