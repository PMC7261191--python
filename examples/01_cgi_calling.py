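"""CpG-island calling on a constructed promoter sequence.

Builds a 2-kb AT-rich chromosome with a 400-nt island-like block covering
the TSS, then calls islands over the [-200, +200] promoter window and prints
the call coordinates and window-composition summary.
"""

from promenh import call_cgis, extract_anchored, window_composition
from promenh.cgi import associate_promoter_cgi
from promenh.simulate import CGI_TILE

# 2-kb background with an island block centred on the TSS at position 1000
background = "AT" * 1000
island = (CGI_TILE * 20)[:400]
genome = {"chr1": background[:800] + island + background[1200:]}

anchored = extract_anchored(genome, "chr1", 1000, "+", 200, 200)
associated, calls = associate_promoter_cgi(anchored)

print(f"promoter CGI-associated: {associated}")
for call in calls:
    print(
        f"  island at [{call.rel_start:+d}, {call.rel_end:+d}) relative to the TSS, "
        f"{call.length} bp, mean GC {call.mean_gc:.1f}%, "
        f"mean CpG obs/exp {call.mean_obs_exp:.2f}"
    )

# the same composition rule, one window at a time
comp = window_composition(island[:100])
print(
    f"first island window: GC {comp.gc_percent:.1f}%, {comp.n_cpg} CpG, "
    f"obs/exp {comp.cpg_obs_exp:.2f}  (thresholds: >=50% and >=0.6 over >=200 bp)"
)

# an AT-rich span yields no calls at all
print(f"calls on pure background: {call_cgis(background)}")
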