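rules:
- name: gene_from_protein_annotation
  category_a: gene
  sem_ab: ENCODES
  dir_ab: FORWARD
  category_b: protein
  sem_bc: ANNOTATED_TO
  dir_bc: FORWARD
  category_c: BIOMEDICAL_CHARACTERISTIC
  derived_sem: ANNOTATED_TO
  candidate_only: false
- name: encodes_chain
  category_a: BIOMOLECULAR_ENTITY
  sem_ab: ENCODES
  dir_ab: FORWARD
  category_b: BIOMOLECULAR_ENTITY
  sem_bc: ENCODES
  dir_bc: FORWARD
  category_c: BIOMOLECULAR_ENTITY
  derived_sem: ENCODES
  candidate_only: false
- name: gene_from_protein_related_entity
  category_a: gene
  sem_ab: ENCODES
  dir_ab: FORWARD
  category_b: protein
  sem_bc: RELATED_TO
  dir_bc: FORWARD
  category_c: BIOMOLECULAR_ENTITY
  derived_sem: RELATED_TO
  candidate_only: false
- name: protein_disorder_candidate
  category_a: protein
  sem_ab: ENCODES
  dir_ab: REVERSE
  category_b: gene
  sem_bc: ANNOTATED_TO
  dir_bc: FORWARD
  category_c: genetic_disorder
  derived_sem: ANNOTATED_TO
  candidate_only: true
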