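"""Published orthogonal-concordance counts for the assay validation studies.

These are the raw agreement counts from the clinical validation studies
(orthogonal NGS, FISH, PCR and blank-sample confirmations).  They are
inputs to the agreement statistics — the percentages are always recomputed
from the counts, never stored.
"""

from __future__ import annotations

from .agreement import AgreementTable

# study name -> (concordant, reference total)
CONCORDANCE_COUNTS: dict[str, tuple[int, int]] = {
    "snv_strong_clinical_ppa": (35, 36),
    "hotspot_ppa": (116, 119),
    "all_alterations_ppa": (727, 855),
    "msi_ppa": (79, 80),
    "msi_npa": (142, 143),
    "amplification_ppa": (121, 140),
    "translocation_ppa": (42, 51),
    "alk_translocation_ppa": (13, 14),
    "lob_confirmation": (60, 63),
}


def concordance_table(study: str) -> AgreementTable:
    """Positive-agreement table for a named validation study."""
    k, n = CONCORDANCE_COUNTS[study]
    return AgreementTable(tp=k, fn=n - k)
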