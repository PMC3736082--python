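"""Published reference results used for validating the CEA layer.

``REFERENCE_BASE_CASE`` holds the published base-case discounted cost
(2010 R$) and discounted QALYs per woman for the seven screening
strategies A-G.  The pairs are used to validate the dominance and
frontier-ordering algorithm: running :func:`bcscreen.cea.efficiency_frontier`
on them must recover the published non-dominated ordering
(A=1, C=2, B=3, F=4, with D, E and G dominated).
"""

REFERENCE_BASE_CASE: list[tuple[str, float, float]] = [
    ("A", 2075.0, 14.498),  # usual care
    ("B", 2318.0, 14.546),  # SFM annual
    ("C", 2125.0, 14.532),  # SFM every 2 years
    ("D", 2564.0, 14.548),  # FFDM annual
    ("E", 2259.0, 14.533),  # FFDM every 2 years
    ("F", 2393.0, 14.549),  # FFDM (<50) + SFM (50-69), annual
    ("G", 2254.0, 14.538),  # FFDM (<50) annual + SFM (50-69) biennial
]
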