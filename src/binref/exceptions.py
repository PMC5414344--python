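"""Exception hierarchy.

``BinrefError`` is the base for every error raised on bad user data; the
CLI maps it to exit status 1 (usage errors exit 2 via click).
"""


class BinrefError(Exception):
    """Base class for data and usage errors raised by binref."""


class FastaError(BinrefError):
    """Malformed FASTA input (duplicate ids, empty or non-IUPAC sequence)."""


class TableError(BinrefError):
    """Malformed CSV table input (non-numeric or negative cells, bad layout)."""
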