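# Default checkpoint-signaling motif patterns (bracket notation; x = any residue).
# acceptor_offset is the 1-based position of the phospho-acceptor within the match.
# These are conventional consensus definitions and are meant to be overridden
# with a custom config (or a curated acceptor-position list) where a better
# inventory exists.
- name: MELT
  pattern: "[MILV][ED][LIVM]T"
  acceptor_offset: 4
- name: MELT_strict
  pattern: "MELT"
  acceptor_offset: 4
- name: SHT
  pattern: "SHT"
  acceptor_offset: 3
- name: proline_directed
  pattern: "[ST]P"
  acceptor_offset: 1
- name: aurora_b
  pattern: "[RK]x[ST]"
  acceptor_offset: 3
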