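"""Interparticle repulsion: a hard-sphere structure factor with decoupling.

Computes the scattering of an ellipsoid of revolution (semi-axes 50, 50,
100 Å) with and without a Percus–Yevick hard-sphere structure factor
(hard-sphere radius 70 Å, volume fraction η = 0.2).  Because the particle
is nonspherical, the decoupling approximation β(q) = ⟨A(q)⟩²/P(q) damps the
structure-factor modulation.  Repulsion suppresses the forward scattering
by the compressibility factor S(0) = (1−η)⁴/(1+2η)² ≈ 0.209, while p(r) —
a single-particle property — is unchanged by construction.
"""

import numpy as np

import sasbead as sb

spec = sb.ModelSpec(
    subunits=(sb.Subunit("ellipsoid_triaxial", (50.0, 50.0, 100.0)),), seed=3
)
cloud = sb.build_model(spec)
pd = sb.pair_histogram(cloud)
q = np.linspace(0.001, 0.5, 400)

dilute = sb.intensity_from_histogram(pd, q)
s_raw = sb.hard_sphere_sf(q, r_hs=70.0, eta=0.2)
beta = sb.decoupling_beta(cloud, q)
interacting = sb.apply_structure_factor(dilute, s_raw, beta)

print(f"ellipsoid 50/50/100 Å:  Rg = {pd.rg:.2f} Å,  Dmax = {pd.dmax:.2f} Å")
print(f"PY S(q->0)            = {s_raw[0]:.4f}  (compressibility limit 0.2090)")
print(f"beta(q=0.05)          = {beta[np.searchsorted(q, 0.05)]:.3f}  (<1: anisotropy)")
print(f"I(q_min)/P(q_min)     = {interacting.I[0] / dilute.P[0]:.4f}  (forward suppression)")
print("p(r) is identical with and without the structure factor by contract.")
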