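"""Compare the scattering of a sphere and an elongated cylinder.

Builds two bead models — a sphere of radius 50 Å and a cylinder of radius
50 Å and length 400 Å — and runs the full pipeline: p(r), P(q), simulated
noisy data, PDB export and comparison plots.  The pair distance
distribution is the real-space fingerprint: the sphere's p(r) is a
single-peaked bell ending at Dmax = 2R ≈ 100 Å, while the cylinder's has a
long tail out to its body diagonal ≈ 412 Å, and its larger Rg reflects the
elongation.
"""

import sasbead as sb

sphere = sb.ModelSpec(subunits=(sb.Subunit("sphere", (50.0,)),), seed=1)
cylinder = sb.ModelSpec(subunits=(sb.Subunit("cylinder", (50.0, 400.0)),), seed=2)

config = sb.RunConfig(models=(sphere, cylinder), seed=1)
result = sb.run(config, output_dir="example_output/sphere_vs_cylinder")

for label, res in zip(("sphere R=50 Å", "cylinder R=50 Å, L=400 Å"), result.models):
    print(
        f"{label:28s}  N = {len(res.cloud):4d}   "
        f"Rg = {res.pr.rg:6.2f} Å   Dmax = {res.pr.dmax:6.2f} Å"
    )
print(f"\nOutputs (curves, simulated data, PDB, plots): {result.output_dir}")
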