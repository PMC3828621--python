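"""Temperature sweep on one synthetic protein.

Generates the default synthetic scenario (150 sites, 100 natural sequences,
500 designs per temperature) and prints, per design temperature: mean site
entropy, mean KL and rank-ordered KL against the natural alignment, and the
entropy-RSA correlation. The natural alignment's values and the split-half
control provide the reference points.
"""

from designvar import (
    SyntheticSpec,
    build_site_map,
    column_counts,
    generate_design_alignment,
    generate_natural_alignment,
    kl_divergence,
    mean_entropy,
    per_protein_mean,
    rank_ordered_kl,
    sample_rsa_profile,
    site_entropy,
    site_frequencies,
    split_half_control,
)
from designvar.exposure_analysis import entropy_rsa_correlation, join_site_table

spec = SyntheticSpec(seed=1)
rsa = sample_rsa_profile(spec)
natural, _truth = generate_natural_alignment(spec, rsa)
smap = build_site_map(natural)

nat_counts = column_counts(natural, smap)
nat_H = site_entropy(site_frequencies(nat_counts))
q = site_frequencies(nat_counts, pseudocount=True)
nat_table = join_site_table({"nat": nat_H}, nat_counts.positions, rsa)

print(f"natural mean entropy: {mean_entropy(nat_H):.3f} nats")
print(f"natural entropy-RSA correlation: "
      f"{entropy_rsa_correlation(nat_table, 'nat').coefficient:.3f}")
print(f"split-half control KL: {split_half_control(natural, smap, seed=1):.3f} nats")
print()
print(f"{'T':>5} {'meanH':>6} {'KL':>6} {'rankKL':>7} {'r':>6}")
for T in spec.temperatures:
    design, _t = generate_design_alignment(spec, rsa, T)
    counts = column_counts(design, smap)
    H = site_entropy(site_frequencies(counts))
    p = site_frequencies(counts, pseudocount=True)
    table = join_site_table({"d": H}, counts.positions, rsa)
    try:
        r = f"{entropy_rsa_correlation(table, 'd').coefficient:6.3f}"
    except ValueError:
        r = "  n/a "  # near-constant entropy at very low T
    print(
        f"{T:>5g} {mean_entropy(H):6.3f} "
        f"{per_protein_mean(kl_divergence(p, q)):6.3f} "
        f"{per_protein_mean(rank_ordered_kl(p, q)):7.4f} {r}"
    )
print()
print("Design entropy rises monotonically with T and brackets the natural value;")
print("the rank-ordered KL dips at an intermediate T where the designed frequency")
print("shapes best match the natural ones.")
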