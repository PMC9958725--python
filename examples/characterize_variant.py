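"""Reconstruct mature nisin E from its published differences and report
how it relates to nisin A: edit names, identity, hinge, and masses.

The edit list uses reference (nisin A) numbering; the observed 3100.8 Da
MALDI mass is explained by eight Ser/Thr dehydrations, the hallmark of
lanthipeptide maturation.
"""

from lantipipe import (
    NISIN_A_CORE,
    apply_edits,
    diff_variants,
    hinge_region,
    infer_dehydrations,
    peptide_mass,
)
from lantipipe.alignment import global_align, percent_identity
from lantipipe.refdata import NISIN_E_EDITS

nisin_e = apply_edits(NISIN_A_CORE, NISIN_E_EDITS)
print(f"reconstructed nisin E ({len(nisin_e)} aa): {nisin_e}")

diff = diff_variants(NISIN_A_CORE, nisin_e)
print(f"{len(diff)} differences vs nisin A: {', '.join(diff.name_strings)}")

pid = percent_identity(global_align(NISIN_A_CORE, nisin_e))
print(f"identity to nisin A: {pid:.1f}%  (24 matches over 32 shared columns)")
print(f"hinge region: {hinge_region(nisin_e)}  (nisin A: NMK)")

mass = peptide_mass(nisin_e, "average")
inference = infer_dehydrations(nisin_e, observed_mass=3100.8, tolerance=1.5)
print(f"unmodified average mass: {mass:.1f} Da")
print(
    f"observed 3100.8 Da -> {inference.n_dehydrations} dehydrations "
    f"(predicted {inference.predicted_mass:.1f} Da, "
    f"residual {inference.residual:+.1f} Da)"
)
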