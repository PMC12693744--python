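"""8-digit cage-position identifiers and their EAN-13 embedding.

A nest site is named by four zero-padded two-digit fields, concatenated in
order: house (1-25), cage (1-4), group (1-99), nest (1-6).  The string form
("01012104" = house 1, cage 1, group 21, nest 4) is the Uid key of every
egg record.  The field for cage occupies two digits although its range is
1-4; the layout is kept as designed.

The identifier travels on the cage label as an EAN-13 barcode: a fixed
4-digit prefix (default "2000", in the restricted-distribution numbering
space, so codes never collide with retail articles) plus the 8 payload
digits form the 12 data digits, and the 13th digit is the standard
weighted-sum check digit.
"""

from __future__ import annotations

from dataclasses import dataclass

__all__ = [
    "PositionCode",
    "PositionFormatError",
    "PositionRangeError",
    "ForeignBarcodeError",
    "parse_position",
    "format_position",
    "ean13_check_digit",
    "embed_in_ean13",
    "extract_from_ean13",
    "DEFAULT_PREFIX",
]

DEFAULT_PREFIX = "2000"

_RANGES = {"house": (1, 25), "cage": (1, 4), "group": (1, 99), "nest": (1, 6)}


class PositionFormatError(ValueError):
    """Uid string is not exactly 8 decimal digits."""


class PositionRangeError(ValueError):
    """A parsed field falls outside its allowed range."""


class ForeignBarcodeError(ValueError):
    """A valid EAN-13 whose prefix does not belong to this installation."""


@dataclass(frozen=True)
class PositionCode:
    house: int
    cage: int
    group: int
    nest: int

    def __post_init__(self) -> None:
        for name, (lo, hi) in _RANGES.items():
            v = getattr(self, name)
            if not lo <= v <= hi:
                raise PositionRangeError(
                    f"{name}={v} outside allowed range [{lo}, {hi}]"
                )

    @property
    def uid(self) -> str:
        return format_position(self)


def parse_position(uid: str) -> PositionCode:
    """Parse an 8-digit Uid into its four range-checked fields."""
    if not isinstance(uid, str) or len(uid) != 8 or not uid.isdigit():
        raise PositionFormatError(f"uid must be exactly 8 decimal digits, got {uid!r}")
    return PositionCode(
        house=int(uid[0:2]), cage=int(uid[2:4]), group=int(uid[4:6]), nest=int(uid[6:8])
    )


def format_position(code: PositionCode) -> str:
    """Canonical 8-digit string, two zero-padded digits per field."""
    return f"{code.house:02d}{code.cage:02d}{code.group:02d}{code.nest:02d}"


def ean13_check_digit(data12: str) -> int:
    """Weighted-sum check digit over the 12 data digits (weights 1,3,1,3,...)."""
    if len(data12) != 12 or not data12.isdigit():
        raise ValueError("need exactly 12 data digits")
    s = sum(int(d) * (3 if i % 2 else 1) for i, d in enumerate(data12))
    return (10 - s % 10) % 10


def embed_in_ean13(code: PositionCode, prefix: str = DEFAULT_PREFIX) -> str:
    """Full 13-digit code: prefix + uid + check digit."""
    if len(prefix) != 4 or not prefix.isdigit():
        raise ValueError("prefix must be exactly 4 decimal digits")
    data = prefix + format_position(code)
    return data + str(ean13_check_digit(data))


def extract_from_ean13(ean: str, prefix: str = DEFAULT_PREFIX) -> PositionCode:
    """Recover the position code from a checksum-valid EAN-13."""
    if len(ean) != 13 or not ean.isdigit():
        raise ValueError("EAN-13 must be 13 decimal digits")
    if int(ean[12]) != ean13_check_digit(ean[:12]):
        raise ValueError(f"checksum mismatch in {ean}")
    if ean[:4] != prefix:
        raise ForeignBarcodeError(
            f"barcode prefix {ean[:4]} does not match expected {prefix}"
        )
    return parse_position(ean[4:12])
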