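"""Recover the canonical pose of a randomly misoriented subject.

The alignment chain is: PCA orientation (plate normal to y, notch-bearing
end superior), a frontal-plane refinement rotation, automatic jugular-notch
detection, and translation of the notch to the origin.
"""
from msbmap import (PhantomSpec, align, apply_rigid, generate_phantom,
                    pose_recovery_errors)

phantom = generate_phantom(PhantomSpec(), seed=3, with_volume=False)
misposed = apply_rigid(phantom, rotation_deg=(18.0, -11.0, 24.0),
                       translation_mm=(14.0, -6.0, 9.0))

subject = align(misposed.surfaces)
ang_err, notch_err = pose_recovery_errors(subject, misposed)

print(f"applied rotation magnitude: "
      f"{misposed.truth.applied_transform.rotation_angle_deg():.1f} deg")
print(f"orientation error after alignment: {ang_err:.2f} deg")
print(f"notch localisation error:          {notch_err:.2f} mm")
print(f"manual notch override used:        {subject.manual_override_used}")
# Sub-degree / sub-millimetre errors mean the automatic chain reproduces
# the canonical anatomical frame; the residual reflects how far a
# moment-based orientation can get on a plate with sculpted faces.
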