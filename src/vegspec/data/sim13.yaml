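# Simulated 13-band set: nominal published Sentinel-2 (MSI) band centres and
# FWHM in nm.  These are the public nominal sensor specifications, not a
# tabulated spectral-response measurement; edit to match another sensor model.
name: sim13
bands:
  - {name: B01, centre_nm: 442.7, fwhm_nm: 21.0}
  - {name: B02, centre_nm: 492.4, fwhm_nm: 66.0}
  - {name: B03, centre_nm: 559.8, fwhm_nm: 36.0}
  - {name: B04, centre_nm: 664.6, fwhm_nm: 31.0}
  - {name: B05, centre_nm: 704.1, fwhm_nm: 15.0}
  - {name: B06, centre_nm: 740.5, fwhm_nm: 15.0}
  - {name: B07, centre_nm: 782.8, fwhm_nm: 20.0}
  - {name: B08, centre_nm: 832.8, fwhm_nm: 106.0}
  - {name: B8A, centre_nm: 864.7, fwhm_nm: 21.0}
  - {name: B09, centre_nm: 945.1, fwhm_nm: 20.0}
  - {name: B10, centre_nm: 1373.5, fwhm_nm: 31.0}
  - {name: B11, centre_nm: 1613.7, fwhm_nm: 91.0}
  - {name: B12, centre_nm: 2202.4, fwhm_nm: 175.0}
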