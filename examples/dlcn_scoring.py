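"""Score one patient with the Dutch Lipid Clinic Network criteria.

A patient with tendon xanthomata, premature coronary disease, an LDL-C of
7.0 mmol/L and a confirmed functional mutation: each criterion group
contributes its best-scoring satisfied criterion, the groups sum, and the
total is banded (>8 = definite FH).
"""

from fhdx import DlcnCriteriaInput, compute_friedewald_ldl, score_dlcn
from fhdx.models import DnaMutation

ldl, needs_direct = compute_friedewald_ldl(tc=8.6, hdl=1.4, tg=1.8)
print(f"Friedewald LDL-C estimate: {ldl:.2f} mmol/L "
      f"(direct assay indicated: {needs_direct})")

result = score_dlcn(DlcnCriteriaInput(
    tendon_xanthomata=True,
    personal_premature_cad=True,
    ldl_mmol_per_l=7.0,
    dna_functional_mutation=DnaMutation.yes,
))
print(f"group subscores: {result.group_subscores}")
print(f"total DLCN score: {result.total} -> band: {result.band.value}")
# physical 6 + clinical 2 + LDL 5 + DNA 8 = 21, well above the
# definite threshold (>8): this patient has definite FH.
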