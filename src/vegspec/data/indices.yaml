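# Vegetation-index registry: name + expression over R<nm> tokens.
# R<nm> is the reflectance of the band nearest <nm>; mean(R<lo>:R<hi>) averages
# all bands in the closed range; log is natural.  Standard literature forms.
- name: NDVI
  expression: "(R800 - R670) / (R800 + R670)"
- name: PRI
  expression: "(R531 - R570) / (R531 + R570)"
- name: ARI
  expression: "1/R550 - 1/R700"
- name: mARI
  expression: "(1/R550 - 1/R700) * R800"
- name: WBI
  expression: "R900 / R970"
- name: NDLI
  expression: "(log(1/R1754) - log(1/R1680)) / (log(1/R1754) + log(1/R1680))"
- name: CAI
  expression: "0.5 * (R2000 + R2200) - R2100"
- name: RGRI
  expression: "mean(R600:R699) / mean(R500:R599)"
- name: RVSI
  expression: "(R714 + R752) / 2 - R733"
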