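"""Track conformers along a scripted water-dimer trajectory.

A 20-frame trajectory toggles the dimer's hydrogen bond on a known
schedule; the analysis recovers the conformers, their occupancies, and the
graph of transitions with the bonds formed/broken on each edge.
"""

from mdgraphs import analyze_trajectory, load_params
from mdgraphs.fixtures import TrajectoryScript, make_scripted_trajectory

params, thresholds = load_params()

script = TrajectoryScript(
    base="water_dimer",
    n_frames=20,
    schedule={f: ("break_hbond",) for f in (4, 5, 6, 12, 13)},
)
trajectory, expected_ids = make_scripted_trajectory(script)
registry, transitions, ids = analyze_trajectory(trajectory, params, thresholds)

print(f"frames analyzed : {len(trajectory)}")
print(f"conformers found: {len(registry)} (ground truth {len(set(expected_ids))})")
print(f"id sequence     : {ids}")
for cid, info in sorted(transitions.vertices.items()):
    print(f"  conformer {cid}: {info['percentage']:5.1f} % of frames, "
          f"{sum(1 for b in info['bonds'] if b[0] == 'hbond')} H-bond(s)")
for (i, j), entry in sorted(transitions.edges.items()):
    diff = entry["diff"]
    change = (f"+{len(diff.formed)} formed, -{len(diff.broken)} broken")
    print(f"  transition {i} -> {j}: {entry['count']}x ({change})")

# The two conformers differ only in the O->O hydrogen-bond arc, so each
# transition edge carries exactly that one-bond change; occupancies are
# exact frame fractions and sum to 100%.
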