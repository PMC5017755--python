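"""Check the binomial approximation of the resampling null.

On a purely null GWAS (uniform p-values, nothing planted) the number of
significant genes among a random gene list should follow Binomial(n, p).
This script draws both null distributions at several fixed thresholds and
prints the Spearman rank correlation of their QQ-paired quantiles — the
statistic expected to stay at or above 0.90.
"""

from genescout import (
    background_rate,
    binomial_null_sim,
    build_gene_store,
    compare_nulls,
    load_gwas,
    parse_refflat,
    resampling_null,
    select_canonical,
)
from genescout.synthetic import (
    generate_gene_catalog,
    generate_gwas_summary,
    generate_snp_positions,
    null_study_config,
)

config = null_study_config(seed=1)
catalog = generate_gene_catalog(config)
models, _ = select_canonical(parse_refflat(catalog.refflat_lines))
store = build_gene_store(models, "/tmp/example_null_genes.db")
summary = generate_gwas_summary(catalog, generate_snp_positions(config), config)
index = load_gwas(summary.frame).index()

print(f"store: {store.total_genes} genes; summary: {len(summary.frame)} null SNPs")
print("threshold   background p   QQ Spearman")
for i, threshold in enumerate((1e-2, 1e-3, 1e-4, 1e-5)):
    rate = background_rate(store, index, threshold)
    resampled = resampling_null(
        store, index, list_size=300, iterations=500,
        fixed_threshold=threshold, seed=1000 + i,
    )
    simulated = binomial_null_sim(300, rate.p, iterations=500, seed=1500 + i)
    rho = compare_nulls(resampled, simulated).spearman
    print(f"{threshold:9.0e}   {rate.p:12.4f}   {rho:11.3f}")
# High rank correlation at every threshold justifies replacing the slow
# resampling null by the closed-form binomial when reporting enrichment.
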