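"""Cross-biomarker validation of creatinine-based eGFR lead variants.

A lead variant's eGFRcrea association counts as kidney-function relevant when
an alternative biomarker agrees: nominally significant (p < 0.05) association
with cystatin-based eGFR in the *same* direction, and/or with blood urea
nitrogen in the *opposite* direction (BUN rises as filtration falls).  A
creatinine-metabolism artefact is expected to show neither.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

from .sumstats import AssocRecord

__all__ = ["ValidationResult", "validate_lead_variant", "validation_summary"]

CATEGORIES = ("both", "cys_only", "bun_only", "none")


@dataclass
class ValidationResult:
    cpaid: str
    category: str
    cys_validated: bool
    bun_validated: bool
    cys_missing: bool = False
    bun_missing: bool = False

    @property
    def validated(self) -> bool:
        return self.category != "none"


def _sign(x: float) -> int:
    return int(x > 0) - int(x < 0)


def validate_lead_variant(crea: AssocRecord, cys: AssocRecord | None,
                          bun: AssocRecord | None,
                          alpha: float = 0.05) -> ValidationResult:
    """Classify one lead variant; records must share the same effect allele.

    A missing biomarker record contributes "not validated" and is flagged.
    The boundary p == alpha does not validate (strict "<").
    """
    if crea.beta == 0:
        raise ValueError(f"eGFRcrea effect is zero at {crea.key.cpaid}: "
                         "direction undefined")
    d = _sign(crea.beta)
    cys_ok = (cys is not None and cys.p < alpha and _sign(cys.beta) == d)
    bun_ok = (bun is not None and bun.p < alpha and _sign(bun.beta) == -d)
    if cys_ok and bun_ok:
        cat = "both"
    elif cys_ok:
        cat = "cys_only"
    elif bun_ok:
        cat = "bun_only"
    else:
        cat = "none"
    return ValidationResult(
        cpaid=crea.key.cpaid, category=cat,
        cys_validated=cys_ok, bun_validated=bun_ok,
        cys_missing=cys is None, bun_missing=bun is None,
    )


def validation_summary(results: list[ValidationResult]) -> dict[str, int]:
    """Counts per category; the four counts sum to the input size."""
    counts = Counter(r.category for r in results)
    return {cat: counts.get(cat, 0) for cat in CATEGORIES}
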