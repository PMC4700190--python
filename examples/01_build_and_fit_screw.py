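"""Build a CynD-like spiral and recover its screw parameters.

Generates a coarse-grained dimer, arranges nine copies on the CynD screw
(rise 1.62 nm, twist 77 deg, left-handed), then estimates the screw back
from coordinates alone.  The printed estimate should equal the build
parameters to machine precision, and the diameter should read 11 nm --
the width of CynD helices in electron micrographs.
"""

from spiralscan import (
    CYND_SCREW,
    build_helical_assembly,
    dimers_per_turn,
    estimate_screw_parameters,
    outer_diameter,
)
from spiralscan.synthetic import make_c2_dimer, make_toy_protomer

protomer = make_toy_protomer(
    n_residues=330, radius=55.0, interface_residues=range(55, 73), seed=0
)
dimer = make_c2_dimer(protomer)
assembly = build_helical_assembly(dimer, CYND_SCREW, n_copies=9)

est = estimate_screw_parameters(assembly)
print(f"built with : rise {CYND_SCREW.rise_nm} nm, twist {CYND_SCREW.twist_deg} deg, "
      f"{CYND_SCREW.handedness.value}-handed")
print(f"estimated  : rise {est.rise_nm:.4f} nm, twist {est.twist_deg:.4f} deg, "
      f"{est.handedness.value}-handed (pair spread {est.twist_spread_deg:.2e} deg)")
print(f"dimers/turn: {dimers_per_turn(est.parameters):.4f}  "
      "(4.68 steps of 77 deg per full turn)")
print(f"outer diameter: {outer_diameter(assembly):.2f} nm")
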