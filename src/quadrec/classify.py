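"""Functional categorisation of coding variants.

Every coding variant falls in exactly one of five categories:

* **PTV** — protein-truncating: splice-site variants within +/- 2 bp of an
  exon-intron boundary (as flagged by the upstream annotator), stop-gain,
  stop-loss, and frameshift indels;
* **Dmis** — deleterious missense, ReVe score > 0.7;
* **Tmis** — tolerated missense, ReVe score <= 0.7 (the boundary value 0.7
  is Tmis, never Dmis);
* **synonymous**;
* **nonframeshift** — in-frame indels.

Variants annotated as splice-site on one transcript and synonymous/missense
on another are expected to arrive with ``effect=splice_site`` (most severe
consequence) and are therefore PTVs.
"""

from __future__ import annotations

import enum

from .cohort import AnnotatedVariant, Effect
from .errors import ClassificationError

REVE_DMIS_THRESHOLD = 0.7

_PTV_EFFECTS = {
    Effect.SPLICE_SITE,
    Effect.STOP_GAIN,
    Effect.STOP_LOSS,
    Effect.FRAMESHIFT_INDEL,
}


class FunctionalCategory(str, enum.Enum):
    PTV = "PTV"
    DMIS = "Dmis"
    TMIS = "Tmis"
    SYNONYMOUS = "synonymous"
    NONFRAMESHIFT = "nonframeshift"


def classify(
    v: AnnotatedVariant, *, missing_reve: str = "error"
) -> FunctionalCategory:
    """Assign the variant's functional category.

    Parameters
    ----------
    v:
        Variant with ``effect`` populated (and ``reve_score`` for missense).
    missing_reve:
        ``"error"`` (default) raises :class:`ClassificationError` for a
        missense variant without a ReVe score; ``"tmis"`` falls back to the
        tolerated-missense category.
    """
    if v.effect in _PTV_EFFECTS:
        return FunctionalCategory.PTV
    if v.effect is Effect.MISSENSE:
        if v.reve_score is None:
            if missing_reve == "tmis":
                return FunctionalCategory.TMIS
            raise ClassificationError(f"{v.variant_id}: missense without ReVe score")
        return (
            FunctionalCategory.DMIS
            if v.reve_score > REVE_DMIS_THRESHOLD
            else FunctionalCategory.TMIS
        )
    if v.effect is Effect.SYNONYMOUS:
        return FunctionalCategory.SYNONYMOUS
    if v.effect is Effect.NONFRAMESHIFT_INDEL:
        return FunctionalCategory.NONFRAMESHIFT
    raise ClassificationError(f"{v.variant_id}: unhandled effect {v.effect}")
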