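# Atom-transition map for [13C5/15N2]glutamine tracing.
#
# Carbon is tracked as an intact backbone unit (the C5 skeleton of glutamine
# passes to glutamate and alpha-ketoglutarate; the C4 unit continues to
# fumarate and the oxaloacetate/aspartate pool).  Nucleotide carbon comes from
# PRPP/glycine/CO2 (glucose-derived) and is modeled as unlabeled under the
# glutamine tracer, matching the absence of detectable 13C nucleotide signal.
#
# Nitrogen positions, one entry per nitrogen atom of the molecular formula:
#   gln-N                 glutamine's own amide/amine nitrogens (from medium)
#   glu-N                 glutamate amine nitrogen (glutamine alpha-N via GLS/PPAT)
#   asp-N                 aspartate amine nitrogen (via transamination)
#   gln-amide             amide (gamma) nitrogen transferred at this metabolite's
#                         synthesis step (PPAT for purines, CPS-II for UMP, GMPS)
#   aspartate             nitrogen donated by aspartate at the synthesis step
#   imp-amide             inherited from the IMP amide-derived positions
#   imp-aspartate         inherited from the IMP aspartate-derived position
#   unlabeled             glycine-derived or otherwise untraced nitrogen
metabolites:
  glutamine:
    carbon: {tag: gln-backbone, n_backbone: 5}
    nitrogen: [gln-N, gln-N]
  glutamate:
    carbon: {tag: glu-backbone, n_backbone: 5}
    nitrogen: [glu-N]
  aspartate:
    carbon: {tag: asp-backbone, n_backbone: 4}
    nitrogen: [asp-N]
  alpha-ketoglutarate:
    carbon: {tag: akg-backbone, n_backbone: 5}
    nitrogen: []
  fumarate:
    carbon: {tag: fum-backbone, n_backbone: 4}
    nitrogen: []
  IMP:
    carbon: {tag: unlabeled, n_backbone: 0}
    nitrogen: [gln-amide, gln-amide, aspartate, unlabeled]
  AMP:
    carbon: {tag: unlabeled, n_backbone: 0}
    nitrogen: [imp-amide, imp-amide, imp-aspartate, unlabeled, aspartate]
  GMP:
    carbon: {tag: unlabeled, n_backbone: 0}
    nitrogen: [imp-amide, imp-amide, imp-aspartate, unlabeled, gln-amide]
  UMP:
    carbon: {tag: unlabeled, n_backbone: 0}
    nitrogen: [gln-amide, aspartate]
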