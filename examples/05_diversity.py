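"""Pairwise Tanimoto distributions and sphere-exclusion subset selection."""

from abxspace import compute_fingerprint, diverse_subset, pairwise_distribution, standardize

# a congeneric alkyl series (one chemotype) vs a structurally mixed set
series = ["C" * k + "CCc1ccc(C(=O)O)cc1" for k in range(10)]
mixed = ["CCO", "c1ccc2ccccc2c1", "CC(=O)Nc1ccccc1", "C1CCNCC1", "CCCCCCCC",
         "O=S(=O)(N)c1ccccc1", "c1ccncc1", "OCC(O)CO", "CC(=O)O", "NCc1ccccc1"]

fp_series = [compute_fingerprint(standardize(s, str(i))) for i, s in enumerate(series)]
fp_mixed = [compute_fingerprint(standardize(s, str(i))) for i, s in enumerate(mixed)]

d_series = pairwise_distribution(fp_series)
d_mixed = pairwise_distribution(fp_mixed)
print(f"congeneric series: similarity peak {d_series.peak:.3f} over {d_series.n_pairs} pairs")
print(f"mixed set:         similarity peak {d_mixed.peak:.3f} over {d_mixed.n_pairs} pairs")

kept = diverse_subset(fp_series, threshold=0.65, seed=0)
print(f"\nsphere exclusion at 0.65 keeps {len(kept)}/{len(series)} of the congeneric series")
print("A high similarity peak marks a chemotype-biased set; the retained subset")
print("contains no pair at or above the 0.65 Tanimoto threshold.")
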