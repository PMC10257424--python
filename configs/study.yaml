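# Example synthetic study: three tumour models, two arms, all modalities.
# Run with:  mpmri run --config configs/study.yaml
seed: 2024
outdir: scratch/study_yaml
matrix: 64            # acquisition matrix (default protocol uses 128 over 30 mm)
mre_matrix: 64        # elastography matrix over a 19.2 mm FOV
noise_sigma: 0.02     # Rician noise sd relative to mean viable signal (~SNR 50)
mre_noise_sigma: 0.0
write_maps: false
histology_block_px: 64
histology_window_voxels: 8

groups:
  - name: lowHA            # fast-growing, HA-poor model
    n_per_arm: 6
    ha_density: 0.08
    ha_sd: 0.03
    baseline:
      t1_ms: 1800.0
      t2_ms: 50.0
      mt_attenuation: 0.36
      adc: 750.0
      r2star_s: 70.0
      g_d_kpa: 4.5
      g_l_kpa: 1.8
      proton_density: 1.0
    effects_pct: {}        # treatment slows growth but leaves the MRI parameters
    growth_saline_pct: 40.0
    growth_treated_pct: 15.0

  - name: highHA           # HA-overexpressing model: broad multiparametric response
    n_per_arm: 6
    ha_density: 0.35
    ha_sd: 0.06
    baseline:
      t1_ms: 2000.0
      t2_ms: 60.0
      mt_attenuation: 0.30
      adc: 900.0
      r2star_s: 55.0
      g_d_kpa: 4.0
      g_l_kpa: 1.6
      proton_density: 1.0
    effects_pct:
      t1_ms: -10.0
      t2_ms: -12.0
      mt_attenuation: 18.0
      adc: -15.0
      r2star_s: 20.0
    growth_saline_pct: 45.0
    growth_treated_pct: 5.0

  - name: collagen         # collagen-dense model: diffusion + viscoelastic response
    n_per_arm: 6
    ha_density: 0.12
    ha_sd: 0.04
    baseline:
      t1_ms: 1900.0
      t2_ms: 55.0
      mt_attenuation: 0.34
      adc: 820.0
      r2star_s: 60.0
      g_d_kpa: 5.0
      g_l_kpa: 2.0
      proton_density: 1.0
    effects_pct:
      adc: -20.0
      g_d_kpa: 35.0
      g_l_kpa: 35.0
    growth_saline_pct: 34.0
    growth_treated_pct: 10.0
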