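{
 "defaults": {
  "aa_charge_change": 0.0,
  "aa_hydrophobicity_change": 0.0,
  "aa_polarity_change": 0.0,
  "aa_volume_change": 0.0,
  "alt_aa_frequency": 0.0,
  "blosum62": 0.0,
  "cadd_raw": 0.1,
  "cdna_position": 0.0,
  "cds_position": 0.0,
  "chromatin_state": 0.0,
  "cpg_density": 0.02,
  "dann_score": 0.1,
  "disorder_score": 0.0,
  "distance_to_splice_site": 0.0,
  "distance_to_tss": 0.0,
  "domain_conservation": 0.0,
  "encode_dnase": 0.0,
  "encode_h3k27ac": 0.0,
  "encode_h3k4me1": 0.0,
  "encode_h3k4me3": 0.0,
  "esp_af": 0.0,
  "exon_number": 0.0,
  "fathmm_score": 0.1,
  "fitcons_score": 0.1,
  "gc_content": 0.42,
  "gene_length": 0.0,
  "gerp_n": 0.0,
  "gerp_rs": 0.0,
  "gerp_s": 0.0,
  "gnomad_af": 0.0,
  "grantham_distance": 0.0,
  "in_pfam_domain": 0.0,
  "intron_number": 0.0,
  "lamin_b1_signal": 0.0,
  "loeuf": 1.0,
  "mamphylop": 0.0,
  "methylation_level": 0.0,
  "mirna_target_score": 0.0,
  "missense_z": 0.0,
  "mmsp_acceptor_score": 0.0,
  "mmsp_donor_score": 0.0,
  "motif_score_change": 0.0,
  "nucleosome_occupancy": 0.0,
  "phastcons_mammal": 0.0,
  "phastcons_primate": 0.0,
  "phastcons_vertebrate": 0.0,
  "phylop_mammal": 0.0,
  "phylop_primate": 0.0,
  "phylop_vertebrate": 0.0,
  "pli": 0.0,
  "polyphen_hvar": 0.1,
  "population_max_af": 0.0,
  "priphylop": 0.0,
  "protein_position": 0.0,
  "ref_aa_frequency": 0.0,
  "relative_cds_position": 0.5,
  "relative_protein_position": 0.5,
  "remap_overlap": 0.0,
  "replication_timing": 0.0,
  "sift_score": 1.0,
  "splice_ai_acceptor_gain": 0.0,
  "splice_ai_acceptor_loss": 0.0,
  "splice_ai_donor_gain": 0.0,
  "splice_ai_donor_loss": 0.0,
  "synonymous_z": 0.0,
  "tf_binding_count": 0.0,
  "thousand_genomes_af": 0.0,
  "transmembrane_region": 0.0,
  "verphylop": 0.0
 },
 "version": "1.0"
}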