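"""Shared fixtures: synthetic worlds built once per session.

All inputs are generated programmatically — no data files ship with the
test suite.
"""

from __future__ import annotations

from types import SimpleNamespace

import pytest

from genescout import (
    GwasIndex,
    build_gene_store,
    build_snp_store,
    load_gwas,
    parse_refflat,
    select_canonical,
)
from genescout.synthetic import (
    PlantedSignal,
    SyntheticConfig,
    generate_gene_catalog,
    generate_gwas_summary,
    generate_ld_panel,
    generate_ld_panels,
    generate_snp_positions,
    null_study_config,
    planted_study_config,
)


@pytest.fixture(scope="session")
def null_study(tmp_path_factory):
    """~2,000-gene store plus a null (uniform-p) GWAS index, seed 1."""
    config = null_study_config(seed=1)
    catalog = generate_gene_catalog(config)
    models, excluded = select_canonical(parse_refflat(catalog.refflat_lines))
    assert not excluded
    db = tmp_path_factory.mktemp("null_study") / "genes.db"
    store = build_gene_store(models, db)
    summary = generate_gwas_summary(catalog, generate_snp_positions(config), config)
    index = load_gwas(summary.frame).index()
    return SimpleNamespace(
        config=config, catalog=catalog, models=models, store=store, index=index
    )


@pytest.fixture(scope="session")
def planted_world(tmp_path_factory):
    """500-gene single-chromosome world with a pruned reference panel.

    The GWAS summary for this world keeps every fourth panel site
    (array-style typing); each recovery replicate generates its own
    summary with freshly planted signals.
    """
    config = planted_study_config(seed=5)
    catalog = generate_gene_catalog(config)
    models, _ = select_canonical(parse_refflat(catalog.refflat_lines))
    root = tmp_path_factory.mktemp("planted_world")
    store = build_gene_store(models, root / "genes.db")
    panel = generate_ld_panel(config, 1)
    snp_store = build_snp_store([panel], root / "snps.db")
    return SimpleNamespace(
        config=config,
        catalog=catalog,
        models=models,
        store=store,
        panel=panel,
        snp_store=snp_store,
    )


@pytest.fixture(scope="session")
def small_world(tmp_path_factory):
    """Tiny two-chromosome world (50 genes, dense enough for planting)."""
    config = SyntheticConfig(
        seed=9,
        n_genes=50,
        n_chromosomes=2,
        chrom_length_bp=1_500_000,
        n_snps_per_chrom=8_000,
        n_samples=60,
        planted_genes=(PlantedSignal("GENE00003", n_signals=2, p_value=1e-15),),
    )
    catalog = generate_gene_catalog(config)
    models, _ = select_canonical(parse_refflat(catalog.refflat_lines))
    root = tmp_path_factory.mktemp("small_world")
    store = build_gene_store(models, root / "genes.db")
    panels = generate_ld_panels(config)
    snp_store = build_snp_store(panels, root / "snps.db")
    summary = generate_gwas_summary(
        catalog,
        {p.chromosome: p.positions for p in panels},
        config,
        {p.chromosome: p.snp_ids for p in panels},
    )
    table = load_gwas(summary.frame)
    return SimpleNamespace(
        config=config,
        catalog=catalog,
        models=models,
        store=store,
        panels=panels,
        snp_store=snp_store,
        summary=summary,
        table=table,
        index=table.index(),
    )
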