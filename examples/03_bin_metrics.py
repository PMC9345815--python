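"""Purity and centrality of a spectral bin.

Purity measures the spread of m/z inside a bin window (1 = all signal
at a single m/z — one underlying mass signal); centrality measures how
close the abundance-weighted mean m/z sits to the bin center (low
centrality warns the signal is near a bin edge).
"""

from fiebin import compute_bin_stats

# a clean bin: one ion with slight scan-to-scan m/z drift
clean = compute_bin_stats(
    [(133.01416, 900.0), (133.01415, 850.0), (133.01417, 920.0)],
    width=0.01,
    center=133.01,
)
print(f"clean bin:    purity={clean.purity:.4f} centrality={clean.centrality:.4f}")

# a contaminated bin: two distinct mass signals share the window
mixed = compute_bin_stats(
    [(133.0141, 900.0), (133.0149, 700.0)],
    width=0.01,
    center=133.01,
)
print(f"mixed bin:    purity={mixed.purity:.4f} centrality={mixed.centrality:.4f}")

# an edge bin: single signal sitting right at the window boundary
edge = compute_bin_stats([(133.0149, 900.0)], width=0.01, center=133.01)
print(f"edge bin:     purity={edge.purity:.4f} centrality={edge.centrality:.4f}")
# The mixed bin's low purity flags likely co-occurrence of two signals;
# the edge bin is pure but its low centrality warns the signal may be
# split with the neighbouring bin.
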