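# Default bacterial single-copy marker set (43 markers).
#
# Universal single-copy genes chosen to remain informative for small-genome
# lineages (e.g. the Candidate Phyla Radiation): ribosomal proteins plus a
# few universal non-ribosomal genes.  This list is configuration, not code —
# replace it with a project-specific set where exact fidelity to a given
# study is needed.  Cutoffs are full-sequence bitscore thresholds (bits).
source: default
markers:
  - {model: rpL1,  cutoff: 50.0, marker: rpL1}
  - {model: rpL2,  cutoff: 50.0, marker: rpL2}
  - {model: rpL3,  cutoff: 50.0, marker: rpL3}
  - {model: rpL4,  cutoff: 50.0, marker: rpL4}
  - {model: rpL5,  cutoff: 50.0, marker: rpL5}
  - {model: rpL6,  cutoff: 50.0, marker: rpL6}
  - {model: rpL10, cutoff: 50.0, marker: rpL10}
  - {model: rpL11, cutoff: 50.0, marker: rpL11}
  - {model: rpL13, cutoff: 50.0, marker: rpL13}
  - {model: rpL14, cutoff: 50.0, marker: rpL14}
  - {model: rpL15, cutoff: 50.0, marker: rpL15}
  - {model: rpL16, cutoff: 50.0, marker: rpL16}
  - {model: rpL17, cutoff: 50.0, marker: rpL17}
  - {model: rpL18, cutoff: 50.0, marker: rpL18}
  - {model: rpL19, cutoff: 50.0, marker: rpL19}
  - {model: rpL20, cutoff: 50.0, marker: rpL20}
  - {model: rpL21, cutoff: 50.0, marker: rpL21}
  - {model: rpL22, cutoff: 50.0, marker: rpL22}
  - {model: rpL23, cutoff: 50.0, marker: rpL23}
  - {model: rpL24, cutoff: 50.0, marker: rpL24}
  - {model: rpL27, cutoff: 50.0, marker: rpL27}
  - {model: rpL29, cutoff: 50.0, marker: rpL29}
  - {model: rpL30, cutoff: 50.0, marker: rpL30}
  - {model: rpS2,  cutoff: 50.0, marker: rpS2}
  - {model: rpS3,  cutoff: 50.0, marker: rpS3}
  - {model: rpS4,  cutoff: 50.0, marker: rpS4}
  - {model: rpS5,  cutoff: 50.0, marker: rpS5}
  - {model: rpS6,  cutoff: 50.0, marker: rpS6}
  - {model: rpS7,  cutoff: 50.0, marker: rpS7}
  - {model: rpS8,  cutoff: 50.0, marker: rpS8}
  - {model: rpS9,  cutoff: 50.0, marker: rpS9}
  - {model: rpS10, cutoff: 50.0, marker: rpS10}
  - {model: rpS11, cutoff: 50.0, marker: rpS11}
  - {model: rpS12, cutoff: 50.0, marker: rpS12}
  - {model: rpS13, cutoff: 50.0, marker: rpS13}
  - {model: rpS15, cutoff: 50.0, marker: rpS15}
  - {model: rpS16, cutoff: 50.0, marker: rpS16}
  - {model: rpS17, cutoff: 50.0, marker: rpS17}
  - {model: rpS19, cutoff: 50.0, marker: rpS19}
  - {model: rpS20, cutoff: 50.0, marker: rpS20}
  - {model: infC,  cutoff: 50.0, marker: infC}
  - {model: secY,  cutoff: 50.0, marker: secY}
  - {model: ffh,   cutoff: 50.0, marker: ffh}
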