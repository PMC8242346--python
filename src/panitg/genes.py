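"""The integrin subunit gene (ITG) panel.

The human integrin subunit family comprises 18 alpha-chain and 12
beta-chain genes; this 30-gene panel is the default screening universe
for every stage of the pipeline.
"""

ITG_ALPHA = (
    "ITGA1", "ITGA10", "ITGA11", "ITGA2", "ITGA2B", "ITGA3", "ITGA4",
    "ITGA5", "ITGA6", "ITGA7", "ITGA8", "ITGA9", "ITGAD", "ITGAE",
    "ITGAL", "ITGAM", "ITGAV", "ITGAX",
)

ITG_BETA = (
    "ITGB1", "ITGB1BP1", "ITGB1BP2", "ITGB2", "ITGB3", "ITGB3BP",
    "ITGB4", "ITGB5", "ITGB6", "ITGB7", "ITGB8", "ITGBL1",
)

ITG_PANEL = ITG_ALPHA + ITG_BETA
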