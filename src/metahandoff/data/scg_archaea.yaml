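# Default archaeal single-copy marker set (38 markers).
#
# Ribosomal proteins conserved across archaea (including archaea/eukaryote
# specific r-proteins) plus universal non-ribosomal markers.  Editable
# configuration; cutoffs are full-sequence bitscores (bits).
source: default
markers:
  - {model: arcL2,    cutoff: 50.0, marker: arcL2}
  - {model: arcL3,    cutoff: 50.0, marker: arcL3}
  - {model: arcL4,    cutoff: 50.0, marker: arcL4}
  - {model: arcL5,    cutoff: 50.0, marker: arcL5}
  - {model: arcL6,    cutoff: 50.0, marker: arcL6}
  - {model: arcL7ae,  cutoff: 50.0, marker: arcL7ae}
  - {model: arcL10e,  cutoff: 50.0, marker: arcL10e}
  - {model: arcL13,   cutoff: 50.0, marker: arcL13}
  - {model: arcL14,   cutoff: 50.0, marker: arcL14}
  - {model: arcL15,   cutoff: 50.0, marker: arcL15}
  - {model: arcL15e,  cutoff: 50.0, marker: arcL15e}
  - {model: arcL16,   cutoff: 50.0, marker: arcL16}
  - {model: arcL18,   cutoff: 50.0, marker: arcL18}
  - {model: arcL18e,  cutoff: 50.0, marker: arcL18e}
  - {model: arcL21e,  cutoff: 50.0, marker: arcL21e}
  - {model: arcL22,   cutoff: 50.0, marker: arcL22}
  - {model: arcL24,   cutoff: 50.0, marker: arcL24}
  - {model: arcL24e,  cutoff: 50.0, marker: arcL24e}
  - {model: arcL29,   cutoff: 50.0, marker: arcL29}
  - {model: arcL30,   cutoff: 50.0, marker: arcL30}
  - {model: arcL44e,  cutoff: 50.0, marker: arcL44e}
  - {model: arcS2,    cutoff: 50.0, marker: arcS2}
  - {model: arcS3,    cutoff: 50.0, marker: arcS3}
  - {model: arcS4,    cutoff: 50.0, marker: arcS4}
  - {model: arcS4e,   cutoff: 50.0, marker: arcS4e}
  - {model: arcS5,    cutoff: 50.0, marker: arcS5}
  - {model: arcS6e,   cutoff: 50.0, marker: arcS6e}
  - {model: arcS8,    cutoff: 50.0, marker: arcS8}
  - {model: arcS8e,   cutoff: 50.0, marker: arcS8e}
  - {model: arcS9,    cutoff: 50.0, marker: arcS9}
  - {model: arcS10,   cutoff: 50.0, marker: arcS10}
  - {model: arcS11,   cutoff: 50.0, marker: arcS11}
  - {model: arcS12,   cutoff: 50.0, marker: arcS12}
  - {model: arcS13,   cutoff: 50.0, marker: arcS13}
  - {model: arcS15,   cutoff: 50.0, marker: arcS15}
  - {model: arcS17,   cutoff: 50.0, marker: arcS17}
  - {model: arcS19,   cutoff: 50.0, marker: arcS19}
  - {model: arcS27ae, cutoff: 50.0, marker: arcS27ae}
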