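"""Expected per-site mutation-class frequencies under fitted histories.

Builds the best-supported divergence models for two toad taxon pairs and
prints the expected frequency of each folded site class for one unphased
diploid per taxon, plus a few exact blockwise pattern probabilities.
"""

from orthocoal import (
    DemographicModel,
    SiteClassCounts,
    expected_site_frequencies,
    pattern_probability,
    pattern_probability_marginal,
)

# Subspecies pair: old split, gene flow B->A, B twice the ancestral size.
scabra = DemographicModel(
    "IM2", theta=0.00129, T=12.0, M=0.032, direction="B->A",
    size_factor=2.07, size_target="B",
)
# Allopatric pair: strict divergence, A one fifth of the ancestral size.
orientalis = DemographicModel(
    "Div2", theta=0.00752, T=3.75, size_factor=0.2, size_target="A",
)

for name, model in [("subspecies pair (IM2)", scabra),
                    ("allopatric pair (Div2)", orientalis)]:
    freqs = expected_site_frequencies(model)
    print(f"{name}:")
    for klass in ("kA", "kB", "kAB", "kAABB"):
        print(f"  E[{klass}] = {freqs[klass]:.6f}")
    # kA/kB: heterozygous in one taxon only; kAB: in both; kAABB: fixed
    # difference.  Values are per fourfold-degenerate site.

p0 = pattern_probability(scabra, SiteClassCounts(0, 0, 0, 0), n_sites=150)
p_no_fixed = pattern_probability_marginal(scabra, {"kAABB"}, n_sites=150)
print(f"\nblock of 150 sites, subspecies model:")
print(f"  P(block fully invariant)      = {p0:.4f}")
print(f"  P(block has no fixed difference) = {p_no_fixed:.4f}")
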