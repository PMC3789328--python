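"""Encode and decode isomiR-style variant names against a known miRNA."""

from sharkmir.annotator import KnownMiRNA, decode_name, describe_variant, encode_name

known = KnownMiRNA("fru-miR-126", "TCGTACCGTGAGTAATAATGCG")

variants = {
    "exact copy": known.rep_seq,
    "one base short on the right": known.rep_seq[:-1],
    "one base longer on the right": known.rep_seq + "G",
    "trimmed left, extended right, substitution": (
        (known.rep_seq[1:] + "GG")[:11] + "A" + (known.rep_seq[1:] + "GG")[12:]
    ),
}

for label, detected in variants.items():
    vd = describe_variant(detected, known)
    name = encode_name(known.name, vd)
    print(f"{label:45s} -> {name}")
    back = decode_name(name, known, flank=("", "GGAA"))
    assert back == detected

# L-n/R-n = n bases fewer on that end than the reference; L+n/R+n = more;
# 1ss12TA = one substitution, T->A at position 12 of the detected sequence.
# decode(encode(...)) restores the detected sequence exactly.
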