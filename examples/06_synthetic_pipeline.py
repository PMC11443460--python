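"""Full phenotyping pipeline on synthetic imagery, no trained network.

Simulates three replicate trays at two NaCl doses, renders the frames,
runs the classical reference detector, and computes germination rate,
germination index and mean root length from the detections — then compares
against the simulation's ground truth.
"""

from germkit.dataset_tools import ExperimentConfig
from germkit.phenotype import germination_index, germination_rate, mean_root_length
from germkit.synthetic_data import GrowthModel, SceneSpec, detect_tray_timeline, simulate_tray

config = ExperimentConfig(interval_h=6.0)   # 8 frames per tray keeps this quick
model = GrowthModel()
scene = SceneSpec()

for conc in (30.0, 120.0):
    print(f"--- NaCl {conc:.0f} mmol/L (generator p_germ = {model.p_germ(conc):.2f}) ---")
    for rep in range(3):
        sim = simulate_tray(config, model, conc, seed=20 + rep + int(conc))
        detected = detect_tray_timeline(sim, scene, noise_seed=rep)
        truth = sim.truth_timeline()
        t_final = detected.times[-1]
        print(
            f"tray {rep + 1}: rate {germination_rate(detected, t_final):5.1f}% "
            f"(truth {germination_rate(truth, t_final):5.1f}%), "
            f"index {germination_index(detected):.3f} "
            f"(truth {germination_index(truth):.3f}), "
            f"mean root {mean_root_length(detected, t_final, scene.calibration):.1f} mm"
        )
print()
print("detected rates track the simulated truth to within a seed or two per")
print("tray; the 30 mmol/L dose germinates more and faster than 120 mmol/L.")
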