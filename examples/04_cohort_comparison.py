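"""Control vs pericyte-deficient cohorts: normalized metrics and statistics.

Runs reduced cohorts (2 animals x 3 vessels per genotype; the full design is
3 x 10) through segmentation and quantification, then compares the three
per-vessel metrics with Fisher's LSD and fold changes.
"""

import vesiq as vq

base = vq.steadystate_config()
analysis = vq.AnalysisConfig(run_colocalization=False)

control = vq.generate_cohort(
    vq.control_scenario(master_seed=11, n_animals=2, vessels_per_animal=3), base)
deficient = vq.generate_cohort(
    vq.pericyte_deficient_scenario(master_seed=12, n_animals=2, vessels_per_animal=3), base)

m_ctrl, _, _ = vq.analyze_cohort(control, analysis, genotype="control")
m_defi, _, _ = vq.analyze_cohort(deficient, analysis, genotype="pericyte_deficient")

for metric, unit in (("bl_intensity_per_um2", "counts/um^2"),
                     ("parenchyma_intensity_per_um3", "counts/um^3"),
                     ("vesicles_per_um3", "puncta/um^3")):
    fc = vq.fold_change(m_defi[metric], m_ctrl[metric], seed=0)
    lsd = vq.fishers_lsd({"control": m_ctrl[metric],
                          "deficient": m_defi[metric]}, metric=metric)
    p = lsd.pairwise["p"].iloc[0]
    print(f"{metric} ({unit}):")
    print(f"  control {m_ctrl[metric].mean():10.3f}   deficient {m_defi[metric].mean():10.3f}")
    print(f"  fold change {fc.ratio:7.2f}  (95% CI {fc.ci_low:.2f}-{fc.ci_high:.2f}), "
          f"LSD p = {p:.2e}")
# The deficient scenario accumulates cargo ~100-fold in the basal lamina and
# ~50-fold in the parenchyma while intracellular puncta become rarer — the
# signature of increased transcytotic delivery with reduced vesicular load.
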