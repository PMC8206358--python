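# Tissue-phantom specification for `vista simulate --spec <file>`.
# Any omitted key falls back to the default phantom; pass "default"
# instead of a file to use the built-in four-structure spec.

field_shape: [16, 96, 96]     # (z, y, x) voxels
pixel_size_xy: 160.0          # nm per in-plane pixel
z_step: 1000.0                # nm between z-slices
psf_fwhm_xy: 320.0            # in-plane Gaussian PSF FWHM, nm
seed: 0                       # overridden by --seed on the command line

structures:
  # kind: nucleus | vessel | soma | dendrite | chromosome_void
  # size_nm is the characteristic radius; protein_density is the relative
  # CH3 intensity per voxel; retention is the fraction surviving
  # homogenization (applied to post-expansion renders only).
  - {kind: nucleus,          count: 5, size_nm: 1100, protein_density: 1.0,  retention: 1.0}
  - {kind: chromosome_void,  count: 5, size_nm: 400,  protein_density: 0.35, retention: 1.0}
  - {kind: vessel,           count: 3, size_nm: 350,  protein_density: 1.5,  retention: 1.0}
  - {kind: soma,             count: 4, size_nm: 800,  protein_density: 0.8,  retention: 1.0}
  - {kind: dendrite,         count: 6, size_nm: 170,  protein_density: 0.6,  retention: 1.0}

background:
  gel_ch2_weight: 0.0         # smooth hydrogel CH2 crosstalk (0 = deuterated gel)
  water_oh_weight: 0.0        # uniform water O-H crosstalk (0 = D2O)

noise:
  model: poisson_gaussian     # or: gaussian
  photon_scale: 1000.0        # expected counts per unit intensity (shot noise)
  read_sigma: 0.01            # Gaussian read noise, intensity units
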