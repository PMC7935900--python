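"""Gene sets used throughout the pipeline.

The methionine recycling machinery is summarised by eleven genes with known
hepatic function: six on the salvage route (MTA/SAM recycling back to
methionine) and five on the de novo (remethylation) route. Exhaustion-score
features and the CD3 / cytolytic-effector symbols are the ones the published
model uses; cohorts annotated with different array vocabularies are handled
by :data:`SYMBOL_ALIASES`.
"""

from __future__ import annotations

#: Methionine salvage pathway (MTA-regenerating route).
SALVAGE_GENES: tuple[str, ...] = ("AMD1", "SRM", "SMS", "ENOPH1", "MTAP", "APIP")

#: De novo (homocysteine remethylation) pathway.
DENOVO_GENES: tuple[str, ...] = ("GNMT", "AHCY", "BHMT", "BHMT2", "MTR")

#: All eleven methionine recycling genes.
METHIONINE_GENES: tuple[str, ...] = SALVAGE_GENES + DENOVO_GENES

#: T-cell content normalisers.
CD3_GENES: tuple[str, ...] = ("CD3D", "CD3E", "CD3G")

#: Cytolytic effectors entering the CYT geometric mean.
CYTOLYTIC_GENES: tuple[str, ...] = ("GZMA", "PRF1")

#: Features of the published exhaustion-score model.
PUBLISHED_FEATURES: tuple[str, ...] = ("YARS", "PKM2", "TPI1", "MTHFD2")

#: Offset constant of the published exhaustion-score formula.
PUBLISHED_OFFSET: float = 12.77237

#: DNA methyltransferases compared between T-cell groups in single-cell data.
DNMT_GENES: tuple[str, ...] = ("DNMT1", "DNMT3A", "DNMT3B")

#: Bidirectional symbol aliases across array annotations.
SYMBOL_ALIASES: dict[str, tuple[str, ...]] = {
    "PKM2": ("PKM",),
    "PKM": ("PKM2",),
    "YARS": ("YARS1",),
    "YARS1": ("YARS",),
}


def resolve_symbol(symbol: str, available) -> str | None:
    """Return the name under which ``symbol`` appears in ``available``.

    Tries the symbol itself first, then its aliases. Returns ``None`` when no
    spelling is present.
    """
    if symbol in available:
        return symbol
    for alias in SYMBOL_ALIASES.get(symbol, ()):
        if alias in available:
            return alias
    return None
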