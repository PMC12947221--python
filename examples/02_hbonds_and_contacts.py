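"""Hydrogen-bond occupancy and persistent contacts on a scheduled scene.

Builds a toy scene in which one donor-H-acceptor triple is posed to
satisfy the geometric criteria (H...A <= 2.5 A, D-H-A >= 120 deg) in a
Bernoulli-scheduled 30% of frames, then measures its occupancy and the
persistent-contact classification of the residue pair.
"""

from mdinfonet import contact_map, hbond_table
from mdinfonet import synthetic as syn

scene, schedules = syn.gen_hbond_scene(
    syn.HBondSceneSpec(occupancies=[0.3], n_frames=5000, seed=11))

table = hbond_table([scene])
rec = table.records[0]
print(f"detected bond {rec.donor} -> {rec.acceptor}: "
      f"occupancy {rec.occupancy:.3f} over {table.n_frames} frames")
print(f"  planted schedule realized {schedules[0].mean():.3f} "
      "(bonds below 0.001 frequency would have been dropped)")

agg = table.per_residue_counts()
print("per-residue aggregate:")
print(agg.to_string(index=False))

cm = contact_map([scene])
frac = cm.fraction[0, 1]
print(f"donor/acceptor residue contact fraction {frac:.3f}; persistent at "
      f"the 75% rule: {bool(cm.persistent[0, 1])}")
print("  (heavy atoms stay within the 6 A cutoff even in bond-off "
      "frames: a persistent contact that is hydrogen-bonded only 30% "
      "of the time)")
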