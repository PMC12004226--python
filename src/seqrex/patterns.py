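"""A few published PROSITE motif patterns used in examples and tests.

PROSITE (https://prosite.expasy.org/) notation: residue classes ``[..]``,
negated classes ``{..}``, wildcards ``x``, element separator ``-`` and
bounded repeats ``(n,m)``. Parse these with dialect ``prosite_like``.
"""

# Homeodomain-like nucleotide consensus written as a pattern (sequence-logo
# reading of the human homeodomain binding site).
HOMEODOMAIN_SITE_DNA = "[TC]-A-A-T-[TC]-[AT]"

# PS00141, ASP_PROTEASE: eukaryotic and viral aspartyl proteases active site.
PS00141 = ("[LIVMFGAC]-[LIVMTADN]-[LIVFSA]-D-[ST]-G-[STAV]-[STAPDENQ]"
           "-{GQ}-[LIVMFSTNC]-{EGK}-[LIVMFGTA]")

# PS00134, TRYPSIN_HIS: serine proteases, trypsin family, histidine active site.
PS00134 = "[LIVM]-[ST]-A-[STAG]-H-C"
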