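# Built-in nuclease profiles.
#
# pam_pattern is an IUPAC string read 5'->3' on the protospacer strand.
# pam_side is relative to the protospacer: three_prime for the Cas9 family,
# five_prime for the Cpf1/Cas12a family.
# Cut offsets are in nt from the PAM boundary on the protospacer strand:
# blunt cuts sit `offset` bp 5' of a 3' PAM; staggered Cpf1 cuts nick the
# non-target strand 18 nt and the target strand 23 nt 3' of a 5' PAM.
# The SaCas9/NmCas9 blunt offset and the Cpf1 target-strand offset are
# conventions, not measured values; both are configurable here.
# optimal_spacer_range is the inclusive spacer-length window with robust
# editing activity.
SpCas9:
  pam_pattern: NGG
  pam_side: three_prime
  seed_len: 7
  cut_model: {kind: blunt, offset: 3}
  optimal_spacer_range: [17, 22]
SaCas9:
  pam_pattern: NNGRRT
  pam_side: three_prime
  seed_len: 7
  cut_model: {kind: blunt, offset: 3}
  optimal_spacer_range: [21, 25]
NmCas9:
  pam_pattern: NNNNGATT
  pam_side: three_prime
  seed_len: 7
  cut_model: {kind: blunt, offset: 3}
  optimal_spacer_range: [19, 25]
AsCpf1:
  pam_pattern: TTTN
  pam_side: five_prime
  seed_len: 7
  cut_model: {kind: staggered, non_target_offset: 18, target_offset: 23}
  optimal_spacer_range: [19, 25]
LbCpf1:
  pam_pattern: TTTN
  pam_side: five_prime
  seed_len: 7
  cut_model: {kind: staggered, non_target_offset: 18, target_offset: 23}
  optimal_spacer_range: [19, 25]
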