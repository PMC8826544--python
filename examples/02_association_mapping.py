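"""SNP-trait association mapping on a simulated expression-trait dataset.

Generates genes carrying ramped single-SNP effects, maps every SNP against
every gene with the matrix-form linear engine, and prints the strongest
discoveries with their BH false-discovery rates next to the planted truth.
"""

from nqtl import SimConfig, gen_expression_trait_dataset, map_linear, qq_summary

cfg = SimConfig(n=100, ngs=50, nss=200, n_causal_edges=10, seed=4)
G, E, truth = gen_expression_trait_dataset(cfg)

assoc = map_linear(G, E, p_report_threshold=1e-4)
print(f"tested {assoc.n_tests_total} SNP-gene pairs; "
      f"{len(assoc)} records at p <= {assoc.p_report_threshold:g}")

planted = set(zip(truth.links["snp"], truth.links["trait"]))
top = assoc.records.nsmallest(8, "p")
print("\n snp      gene      beta     t        p          FDR      planted?")
for _, r in top.iterrows():
    mark = "yes" if (r["snp"], r["trait"]) in planted else "no"
    print(f" {r['snp']:<8} {r['trait']:<8} {r['beta']:+.3f}  {r['stat']:+.2f}  "
          f"{r['p']:.2e}  {r['fdr']:.2e}  {mark}")

qq = qq_summary(assoc)
print(f"\nQQ summary over the reported records: max observed -log10 p = "
      f"{qq['observed_neglog10_p'].max():.1f} vs expected "
      f"{qq['expected_neglog10_p'].max():.1f} — the excess over the diagonal "
      "is the planted genetic signal.")
print("Only genes near the top of the effect ramp are detectable; the "
      "smallest planted effects are indistinguishable from noise by design.")
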