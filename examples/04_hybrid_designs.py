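"""Hybrid designs: core columns from a low temperature, surface from a higher one.

Builds a hybrid alignment whose buried and partially-buried columns come from
designs at T=0.3 and whose exposed columns come from designs at T=0.6, then
compares entropy-RSA correlations of the hybrid, the two pure conditions, and
the natural alignment.
"""

from designvar import (
    HybridRecipe,
    SyntheticSpec,
    build_hybrid,
    build_site_map,
    column_counts,
    generate_design_alignment,
    generate_natural_alignment,
    hybrid_correlation_analysis,
    sample_rsa_profile,
    site_entropy,
    site_frequencies,
)
from designvar.exposure_analysis import entropy_rsa_correlation, join_site_table

spec = SyntheticSpec(seed=1)
rsa = sample_rsa_profile(spec)
natural, _ = generate_natural_alignment(spec, rsa)
smap = build_site_map(natural)
core, _ = generate_design_alignment(spec, rsa, T=0.3)
surface, _ = generate_design_alignment(spec, rsa, T=0.6)

hybrid = build_hybrid(core, surface, smap, rsa, HybridRecipe("T=0.3", "T=0.6"))
h_res, n_res = hybrid_correlation_analysis(hybrid, natural, smap, rsa)


def pure_r(aln):
    counts = column_counts(aln, smap)
    ev = site_entropy(site_frequencies(counts))
    table = join_site_table({"d": ev}, counts.positions, rsa)
    return entropy_rsa_correlation(table, "d").coefficient


print("entropy-RSA correlation")
print(f"  natural:            {n_res.coefficient:.3f}")
print(f"  pure T=0.3:         {pure_r(core):.3f}")
print(f"  pure T=0.6:         {pure_r(surface):.3f}")
print(f"  hybrid (0.3 / 0.6): {h_res.coefficient:.3f}")
print()
print("Neither pure condition reproduces the natural core/surface variability")
print("differential; splicing conserved-core columns with variable-surface")
print("columns restores a natural-like correlation.")
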