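"""Mint and decode license-plate identifiers for tsRNA sequences.

A license plate is a reversible, alignment-free identifier: the length in
nucleotides plus a compact token encoding of the sequence. The example
encodes the 39-nt 3' half of tRNA-Thr-TGT.
"""

from tsrnakit import decode_license_plate, encode_license_plate

seq = "TGGTGTCCTTGGAAAAAGGTTTTCATCTCCGGTTTACAA"
plate = encode_license_plate(seq)
print(f"sequence ({len(seq)} nt): {seq}")
print(f"license plate        : {plate}")
print(f"decodes back exactly : {decode_license_plate(plate) == seq}")
# The '39' field is the fragment length; the 16-character code packs the
# sequence 5 nt per 2 characters.
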