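"""The fixed hallmark-of-aging vocabulary used throughout the package.

Eleven of the twelve canonical hallmarks are scored; dysbiosis is excluded
because its pathway signal rests on non-human (microbial) gene targets and
cannot be assessed against a human target list.
"""

from __future__ import annotations

from .errors import ValidationError

HALLMARKS: tuple[str, ...] = (
    "genomic instability",
    "telomere attrition",
    "epigenetic alterations",
    "loss of proteostasis",
    "disabled macroautophagy",
    "deregulated nutrient sensing",
    "mitochondrial dysfunction",
    "cellular senescence",
    "stem cell exhaustion",
    "altered intercellular communication",
    "chronic inflammation",
)

N_HALLMARKS: int = len(HALLMARKS)

_CANONICAL = {h: h for h in HALLMARKS}


def normalize_hallmark(label: str) -> str:
    """Map a free-form hallmark label onto the fixed 11-label vocabulary.

    Case is ignored and underscores/hyphens are treated as spaces, so
    ``"Cellular_Senescence"`` resolves to ``"cellular senescence"``.

    Raises
    ------
    ValidationError
        If the normalized label is not one of the 11 hallmarks (e.g.
        ``"dysbiosis"``, which is deliberately outside the vocabulary).
    """
    key = " ".join(label.strip().lower().replace("_", " ").replace("-", " ").split())
    try:
        return _CANONICAL[key]
    except KeyError:
        raise ValidationError(
            f"unknown hallmark label {label!r}; expected one of the 11-label "
            f"vocabulary {sorted(HALLMARKS)}"
        ) from None
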