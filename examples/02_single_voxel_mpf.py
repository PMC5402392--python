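"""Single-voxel round trip of the single-point synthetic-reference method.

Forward-simulates one white-matter voxel (MPF 13%, T1 1.6 s) through the
MT-weighted sequence, normalizes by the synthetic (zero-power Ernst)
reference, and inverts the ratio for MPF — with deliberately non-ideal
B0 (+80 Hz) and B1 (0.9) to show the field correction at work.
"""

from mpfkit import SinglePointConstraints, default_protocols, \
    mt_spgr_steady_state, solve_mpf_voxel, synthetic_reference

constraints = SinglePointConstraints()
mt_prot = default_protocols()["mt_w"]

f_true, r1_obs, b0, b1 = 0.13, 1 / 1.6, 80.0, 0.9
params = constraints.params_for(f_true, r1_obs)
s_mt = mt_spgr_steady_state(params, mt_prot, b0_offset=b0, b1_scale=b1)
s_ref = synthetic_reference(r1_obs, 1.0, mt_prot, b1_scale=b1)
ratio = s_mt / s_ref
print(f"true MPF        : {100 * f_true:.3f} %")
print(f"MT/reference    : {ratio:.5f}")

f_corr = solve_mpf_voxel(ratio, r1_obs, b0, b1, constraints, mt_prot)
f_naive = solve_mpf_voxel(ratio, r1_obs, 0.0, 1.0, constraints, mt_prot)
print(f"recovered (B0/B1 corrected) : {100 * f_corr:.3f} %")
print(f"recovered (fields ignored)  : {100 * f_naive:.3f} %")
print()
print("With the field maps supplied the inversion recovers the ground truth")
print("to a few 1e-4 percentage points.  Ignoring the fields leaves a bias")
print("(~0.05 pp here, where R1 is known exactly; several tenths of a point")
print("in full map reconstruction, where the VFA fit and the synthetic")
print("reference inherit the wrong B1 as well).")
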