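"""Trace-geometry validation on constructed Cα-only and P-only chains.

An ideal helix passes every check; a P-only chain with bond lengths
4.3 / 6.0 / 8.1 Å trips the short (< 4.4 Å) and long (> 8.0 Å) bounds; a
Cα-Cα distance 3.1 trans-sigma past the mean trips the ±3σ two-window rule.
"""

import emvalid as ev

reference = ev.default_reference()

helix = ev.helix_trace(20)
print("ideal 20-residue helix:")
print("  trace class:", ev.classify_trace(helix).per_chain["A"])
print("  Cα-Cα outliers:", len(ev.caca_distance_outliers(helix, reference).outliers))
print("  pseudo-Ramachandran outliers:",
      len(ev.pseudo_ramachandran(helix, reference).outliers))

ptrace = ev.p_trace(spacing=[4.3, 6.0, 8.1])
findings = ev.pp_distance_outliers(ptrace)
print(f"\nP-only chain with bonds 4.3/6.0/8.1 Å ({findings.n_evaluated} bonds):")
for outlier in findings.outliers:
    print(f"  residues {outlier.residue_a[0]}-{outlier.residue_b[0]}: "
          f"{outlier.distance:.1f} Å -> {outlier.reason}")

import numpy as np

from emvalid.model_checks import Atom, AtomModel, Chain, Residue

distance = reference.caca_trans[0] + 3.1 * reference.caca_trans[1]
bad = AtomModel(chains=[Chain("A", "protein", [
    Residue(number=i + 1, icode="", name="ALA",
            atoms=[Atom("CA", "C", np.array([i * distance, 0.0, 0.0]))])
    for i in range(2)
])])
caca = ev.caca_distance_outliers(bad, reference)
outlier = caca.outliers[0]
print(f"\nCα pair at {outlier.distance:.3f} Å: flagged, nearest class "
      f"{outlier.nearest_class}, {outlier.deviation_sigma:.1f}σ from its mean")
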