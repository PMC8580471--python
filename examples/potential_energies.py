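"""Hand-checkable energies of the five potential terms on toy fixtures.

Builds the deterministic toy configurations and prints each term next to its
closed-form value, so the harmonic forms (stretch, bend, torsion,
aggregation, repulsion) can be verified by eye.
"""

import math

import fibrinbd as fb

params = fb.ModelParameters()
toys = fb.toy_configurations(params)

print("bond stretched 10% beyond 22.5 nm:")
w = fb.stretch_term(toys["strained_bond"], params).energy.W_S
print(f"  W^S = {w:.4e} J   (closed form 1/2 kS (2.25 nm)^2 = "
      f"{0.5 * params.k_S * (2.25e-9) ** 2:.4e} J)")

print("right-angle bend, kB = 1e-18 J/rad^2:")
w = fb.bending_term(toys["right_angle_triple"], params).energy.W_B
print(f"  W^B = {w:.4e} J   (closed form 1/2 kB (pi/2)^2 = "
      f"{0.5 * params.k_B * (math.pi / 2) ** 2:.4e} J)")

print("90-degree dihedral, kT = 1e-23 J/rad^2:")
w = fb.torsion_term(toys["dihedral_quad"], params).energy.W_T
print(f"  W^T = {w:.4e} J   (closed form 1/2 kT (pi/2)^2 = "
      f"{0.5 * params.k_T * (math.pi / 2) ** 2:.4e} J)")

print("parallel fibres zipped at the 16 nm rest separation:")
net = toys["parallel_pair_16nm"]
bonds = fb.nearest_partner_pairs(net, params)
w = fb.aggregation_term(net, bonds, params).energy.W_A
print(f"  {len(bonds)} bonds, W^A = {w:.1e} J (zero at the rest length)")

print("total field of a rest-length straight fibre:")
ff = fb.total_field(toys["rest_fibre"], params)
print(f"  W_total = {ff.energy.W_total:.1e} J, "
      f"max |force| = {abs(ff.forces).max():.1e} N  (global minimum)")
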