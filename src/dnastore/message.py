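"""The bundled demonstration message.

A 377-character excerpt from the abstract of the initial draft analysis of
the human genome, the canonical worked example for this archive format.
Case-folded it uses a 27-symbol alphabet (24 distinct letters, space,
comma, period).
"""

DEMO_MESSAGE = (
    "The human genome holds an extraordinary trove of information about "
    "human development, physiology, medicine and evolution. Here we report "
    "the results of an international collaboration to produce and make "
    "freely available a draft sequence of the human genome. We also present "
    "an initial analysis of the data, describing some of the insights that "
    "can be gleaned from the sequence."
)
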