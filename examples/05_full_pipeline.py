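"""The full pipeline on synthetic defaults: one call, one consolidated report.

Generates promoters and enhancers with planted islands, motifs, CAGE tags
and peaks, runs every analysis stage, and prints the CGI-stratified
comparison table plus the per-CPE overrepresentation calls.
"""

from promenh import SimConfig, run_pipeline

config = SimConfig(seed=1, n_promoters=150, n_enhancers=150)
report = run_pipeline(config)

el = report.elements
print(f"{len(el)} elements annotated "
      f"({(el['kind'] == 'promoter').sum()} promoters, "
      f"{(el['kind'] == 'enhancer').sum()} enhancers)")
print(f"CGI-associated: {el[el['kind'] == 'promoter']['cgi_called'].mean():.1%} "
      f"of promoters, {el[el['kind'] == 'enhancer']['cgi_called'].mean():.1%} of enhancers")

print("\nsignificantly locally overrepresented CPEs (alpha = 0.001):")
sig = report.cpe_results[report.cpe_results["significant"]]
for row in sig.itertuples(index=False):
    print(f"  {row.kind:9s} {row.cpe:5s} n+ = {row.n_plus:4d}  z = {row.z:6.1f}")

print("\nCGI-stratified comparisons (p from Mann-Whitney / Fisher):")
cols = ["comparison", "kind", "n_cgi", "n_non_cgi", "median_cgi", "median_non_cgi", "p"]
print(report.comparisons[cols].to_string(index=False))
# CGI elements come out longer, broader, more ubiquitously expressed, more
# directional and denser in binding events -- the generator's defaults mirror
# those directions, and the pipeline measures them back from raw inputs.
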