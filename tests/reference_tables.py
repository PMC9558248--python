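"""Published reference pattern tables for the predictor this package embeds.

These lists were produced by the predictor's authors with full-precision SVM
weights, before the effect matrix was rounded to two decimals for
publication. On the rounded matrix a handful of entries sit a few milliunits
on the other side of the decision threshold; those cases carry the boundary
flag, and the audit tests accept either verdict for them.
"""

# All 24 published nonamyloid patterns with core 2 (four free positions),
# unrestricted wildcard substitution.
NONAMYLOID_CORE2 = """
PxPxxx PxDxxx xxPPxx xxPDxx xxPGxx xxPKxx
xxPQxx xxDPxx xxDDxx xxDGxx xxDKxx xxDQxx
xxKPxx xxKDxx xxNPxx xxGPxx xxRPxx xxPxEx
xxPxKx xxPxDx xxDxEx xxDxKx xxDxDx xxKxEx
""".split()

# All 43 published amyloid patterns with three free positions, wildcards
# restricted to the hydrophobic class CVLIMPFYW.
AMYLOID_CORE3_HYDROPHOBIC = """
VxIVxx VxIIxx VxILxx VxIFxx VxVVxx VxVIxx VxVLxx IxIVxx
IxIIxx IxILxx IxVVxx IxVIxx CxIVxx CxIIxx CxILxx CxVVxx
CxVIxx LxIVxx LxIIxx LxILxx LxVVxx LxVIxx FxIVxx FxIIxx
FxVVxx MxIVxx MxIIxx MxVVxx WxIVxx WxIIxx GxIVxx YxIVxx
xxIVIx xxIVxV xxIVxC xxIVxI xxIVxF xxIIxV xxIIxC xxILxV
xxVVxV xxVVxC xxVIxV
""".split()

# All 38 published amyloid patterns with five free positions, wildcards
# restricted to hydrophobic-minus-proline CVLIMFYW.
AMYLOID_CORE1_HYDROPHOBIC_NOP = """
Vxxxxx Ixxxxx Cxxxxx Lxxxxx Fxxxxx Mxxxxx Wxxxxx xIxxxx
xFxxxx xYxxxx xVxxxx xWxxxx xLxxxx xCxxxx xxIxxx xxVxxx
xxFxxx xxCxxx xxLxxx xxMxxx xxWxxx xxxVxx xxxIxx xxxLxx
xxxFxx xxxCxx xxxWxx xxxYxx xxxxIx xxxxWx xxxxFx xxxxCx
xxxxYx xxxxxV xxxxxC xxxxxI xxxxxF xxxxxL
""".split()

# The published four amyloid patterns with three free positions under polar
# wildcards (DENQHKR); the same four are reported for all-minus-proline.
AMYLOID_CORE3_POLAR = ["xxIVIx", "xxIVWx", "xxIIIx", "xxVVIx"]

# The 16 published core-4 amyloid patterns (unrestricted wildcards) whose
# fixed slots contain neither valine nor isoleucine.
AMYLOID_CORE4_VI_FREE = """
CxFLWx CxFLFx CxCLWx CxCLFx CxLLWx CxLLFx LxFLWx LxFLFx
LxCLWx LxCLFx LxLLWx LxLLFx FxFLWx FxFLFx FxCLWx CxFLCx
""".split()

# Published example patterns quoted outside the tables.
AMYLOID_CORE4_EXAMPLES = ["xxIYCI", "IFIYxx", "CxVVxC", "xxIVIV", "CxFLWx", "FxFLFx"]
NONAMYLOID_CORE2_EXAMPLES = ["PxDxxx", "xxKxEx", "xxDDxx", "xxPxDx", "xxPKxx"]

# Published headline counts (full-precision sweep).
PUBLISHED_COUNTS = {
    "amyloid_core4_all": 5531,
    "nonamyloid_core2_all": 24,
    "amyloid_core3_small_nonpolar": 411,
    "amyloid_core3_hydrophobic": 43,
    "amyloid_core3_polar": 4,
    "amyloid_core1_hydrophobic_noP": 38,
    "amyloid_core4_vi_free": 16,
}
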