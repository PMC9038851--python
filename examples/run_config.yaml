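# Example fovsharp run configuration (all keys optional; defaults shown).
# Use with:  fovsharp all --config examples/run_config.yaml --out-dir runs/demo

# --- objective arm: simulated phantom reconstruction pairs
n_pairs: 5            # number of random phantoms
fov_large: 423.0      # two-leg FOV diameter, mm
fov_small: 220.0      # single-leg FOV diameter, mm
n_slices: 6           # slices per volume
slice_spacing: 0.4    # reconstruction increment, mm
psf_fwhm: 0.6         # detector-limited in-plane PSF FWHM, mm (FOV-independent)
noise_sd: 10.0        # additive Gaussian noise, HU
dilation_radius_mm: 2.0   # exclusion margin around bone and the air boundary
spline_order: 3       # b-spline order for large->small grid resampling (0-5)
normalization: sum    # slice metric: sum | mean | rss
edge_scope: per-volume    # Otsu scope for significant edges: per-volume | per-slice
edge_source: small    # edge mask from: small | union

# --- subjective arm: simulated reader study
n_exams: 100
n_readers: 3
exclusion_policy: per-segment-pair   # or per-rating
per_reader_tests: false

seed: 0
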