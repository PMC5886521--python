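"""Degenerate-palindrome operator patterns.

A Rex operator is modelled as a palindrome: a 5-bp AT-rich arm (arm 1),
an 8-bp AT-rich spacer allowed to contain at most one G or C, and a
second arm (arm 2) that is the reverse complement of arm 1, optionally
tolerating a single mismatch confined to the last two arm-2 positions.

Patterns are written in a compact text syntax, e.g.::

    WTGWW{WWWWWWWW}-5-4-3-2-1

The part before ``{`` is the arm-1 template over the degenerate alphabet
(``W`` = A or T, ``N`` = any base). The braced block gives the spacer
(its length sets the spacer length; the one-G/C allowance is implied).
The trailing ``-5-4-3-2-1`` suffix spells arm 2 as the complement of
arm-1 positions read backwards; replacing a digit with ``N`` frees the
corresponding arm-2 position, so ``-5-4-3-N-1`` tolerates a mismatch at
arm-2 position 4 and ``-5-4-3-2-N`` at arm-2 position 5. The reserved
token ``"paper-union"`` compiles the union of the three published
variants: at most one mismatch, at either of arm-2 positions 4 and 5.
A stray bracketed citation token (e.g. ``[1]``) after the closing brace
is tolerated and ignored.
"""

from __future__ import annotations

import itertools
import re
from dataclasses import dataclass, field

__all__ = [
    "ArmTemplate",
    "PalindromePattern",
    "WindowMatch",
    "PatternSyntaxError",
    "compile_pattern",
    "expected_arm2",
    "match_window",
    "enumerate_accepted",
    "PAPER_UNION",
]

#: Reserved pattern spec meaning "union of the three published variants".
PAPER_UNION = "paper-union"

_COMPLEMENT = str.maketrans("ACGT", "TGCA")
_DEGENERATE = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "W": frozenset("AT"),
    "N": frozenset("ACGT"),
}
_ARM_LEN = 5


class PatternSyntaxError(ValueError):
    """Raised when a pattern spec string cannot be parsed."""


@dataclass(frozen=True)
class ArmTemplate:
    """Degenerate 5-symbol template for arm 1 of the palindrome."""

    symbols: str

    def __post_init__(self) -> None:
        if len(self.symbols) != _ARM_LEN:
            raise PatternSyntaxError(
                f"arm template must be {_ARM_LEN} symbols, got {self.symbols!r}"
            )
        for s in self.symbols:
            if s not in _DEGENERATE:
                raise PatternSyntaxError(f"unknown arm template code {s!r}")
        if set(self.symbols) == {"N"}:
            raise PatternSyntaxError("arm template of all N is unconstrained")

    def matches(self, arm: str) -> bool:
        """True if a concrete 5-mer satisfies every template position."""
        return len(arm) == _ARM_LEN and all(
            b in _DEGENERATE[s] for s, b in zip(self.symbols, arm)
        )

    def expand(self):
        """Iterate every concrete 5-mer admitted by the template."""
        return (
            "".join(bases)
            for bases in itertools.product(*(sorted(_DEGENERATE[s]) for s in self.symbols))
        )


@dataclass(frozen=True)
class PalindromePattern:
    """Compiled palindromic-operator search model.

    ``allowed_arm2_mismatch_positions`` uses 1-based arm-2 coordinates;
    at most ``max_arm_mismatches`` (0 or 1) mismatches are tolerated,
    each at an allowed position. Arm 1 must satisfy its template exactly.
    """

    arm_template: ArmTemplate
    spacer_len: int = 8
    max_spacer_gc: int = 1
    allowed_arm2_mismatch_positions: frozenset[int] = field(default_factory=frozenset)
    max_arm_mismatches: int = 0

    def __post_init__(self) -> None:
        if not self.allowed_arm2_mismatch_positions <= set(range(1, _ARM_LEN + 1)):
            raise PatternSyntaxError("arm-2 mismatch positions must be in 1..5")
        if self.max_arm_mismatches not in (0, 1):
            raise PatternSyntaxError("at most one arm mismatch is supported")
        if self.max_arm_mismatches > len(self.allowed_arm2_mismatch_positions):
            raise PatternSyntaxError(
                "max_arm_mismatches exceeds the allowed position set"
            )

    @property
    def window_len(self) -> int:
        return 2 * _ARM_LEN + self.spacer_len

    def to_spec(self) -> str:
        """Canonical spec string (always digit/N suffix form)."""
        suffix = "".join(
            "-N" if (6 - p) in self.allowed_arm2_mismatch_positions and self.max_arm_mismatches
            else f"-{p}"
            for p in range(_ARM_LEN, 0, -1)
        )
        return f"{self.arm_template.symbols}{{{'W' * self.spacer_len}}}{suffix}"


@dataclass(frozen=True)
class WindowMatch:
    """Outcome of testing one window against a pattern.

    When ``matched`` is False the remaining fields are reporting-only.
    ``arm_mismatch_position`` is 0 for a perfect palindrome, else the
    1-based arm-2 position carrying the tolerated mismatch.
    """

    matched: bool
    arm_mismatch_position: int = 0
    spacer_gc_count: int = 0


_SPEC_RE = re.compile(
    r"^(?P<arm>[A-Za-z]+)\{(?P<spacer>[A-Za-z]*)\}(?:\[[^\]]*\])?(?P<suffix>(?:-[0-9N])+)$"
)


def _parse_one(spec: str) -> PalindromePattern:
    text = spec.strip()
    if text.count("{") != 1 or text.count("}") != 1 or text.index("{") > text.index("}"):
        raise PatternSyntaxError(f"unbalanced braces in pattern spec {spec!r}")
    m = _SPEC_RE.match(text)
    if m is None:
        raise PatternSyntaxError(f"malformed pattern spec {spec!r}")
    arm = ArmTemplate(m.group("arm").upper())
    spacer = m.group("spacer").upper()
    if spacer.strip("W") != "":
        bad = sorted(set(spacer) - {"W"})
        raise PatternSyntaxError(f"unsupported spacer code(s) {bad} in {spec!r}")
    if not spacer:
        raise PatternSyntaxError(f"empty spacer in {spec!r}")
    tokens = m.group("suffix").lstrip("-").split("-")
    if len(tokens) != _ARM_LEN:
        raise PatternSyntaxError(
            f"arm-2 suffix must list {_ARM_LEN} positions, got {len(tokens)} in {spec!r}"
        )
    allowed: set[int] = set()
    for i, tok in enumerate(tokens):
        arm1_pos = _ARM_LEN - i  # printed order is 5-4-3-2-1
        arm2_pos = 6 - arm1_pos
        if tok == "N":
            allowed.add(arm2_pos)
        elif tok != str(arm1_pos):
            raise PatternSyntaxError(
                f"unexpected suffix token {tok!r} at slot {arm1_pos} in {spec!r}"
            )
    return PalindromePattern(
        arm_template=arm,
        spacer_len=len(spacer),
        max_spacer_gc=1,
        allowed_arm2_mismatch_positions=frozenset(allowed),
        max_arm_mismatches=1 if allowed else 0,
    )


def compile_pattern(spec: str) -> PalindromePattern:
    """Compile a pattern spec string into an executable matcher.

    ``"paper-union"`` compiles to the union of the three published
    variants: one tolerated arm-2 mismatch at position 4 or 5.
    """
    if spec.strip().lower() == PAPER_UNION:
        return PalindromePattern(
            arm_template=ArmTemplate("WTGWW"),
            spacer_len=8,
            max_spacer_gc=1,
            allowed_arm2_mismatch_positions=frozenset({4, 5}),
            max_arm_mismatches=1,
        )
    return _parse_one(spec)


def _check_dna(seq: str, what: str = "sequence") -> str:
    s = seq.upper()
    bad = set(s) - set("ACGT")
    if bad:
        raise ValueError(f"{what} contains non-ACGT character(s) {sorted(bad)}")
    return s


def expected_arm2(arm1: str) -> str:
    """Reverse complement of a concrete arm-1 5-mer (the perfect arm 2)."""
    s = _check_dna(arm1, "arm1")
    if len(s) != _ARM_LEN:
        raise ValueError(f"arm1 must be {_ARM_LEN} bases, got {len(s)}")
    return s.translate(_COMPLEMENT)[::-1]


def match_window(window: str, p: PalindromePattern) -> WindowMatch:
    """Decide membership of one concrete window.

    The window matches iff (a) its first five bases satisfy the arm
    template, (b) the spacer carries at most ``max_spacer_gc`` G/C
    bases, and (c) the last five bases equal the reverse complement of
    the first five, up to ``max_arm_mismatches`` mismatches at allowed
    arm-2 positions.
    """
    w = _check_dna(window, "window")
    if len(w) != p.window_len:
        raise ValueError(f"window must be {p.window_len} bases, got {len(w)}")
    arm1 = w[:_ARM_LEN]
    spacer = w[_ARM_LEN : _ARM_LEN + p.spacer_len]
    arm2 = w[_ARM_LEN + p.spacer_len :]
    gc = sum(b in "GC" for b in spacer)
    if not p.arm_template.matches(arm1):
        return WindowMatch(False, 0, gc)
    if gc > p.max_spacer_gc:
        return WindowMatch(False, 0, gc)
    mismatches = [
        i + 1 for i, (a, b) in enumerate(zip(expected_arm2(arm1), arm2)) if a != b
    ]
    if len(mismatches) > p.max_arm_mismatches:
        return WindowMatch(False, 0, gc)
    if any(pos not in p.allowed_arm2_mismatch_positions for pos in mismatches):
        return WindowMatch(False, 0, gc)
    return WindowMatch(True, mismatches[0] if mismatches else 0, gc)


def _admissible_spacers(length: int, max_gc: int):
    for bases in itertools.product("ACGT", repeat=length):
        if sum(b in "GC" for b in bases) <= max_gc:
            yield "".join(bases)


def enumerate_accepted(p: PalindromePattern, cap: int = 2_000_000) -> set[str]:
    """Exact set of windows accepted in forward orientation.

    Built by direct product of arm-1 expansions, admissible spacers and
    admissible arm-2 variants; raises if the product exceeds ``cap``
    (sample windows instead for such patterns).
    """
    arms = list(p.arm_template.expand())
    n_spacers = sum(1 for _ in _admissible_spacers(p.spacer_len, p.max_spacer_gc))
    per_arm2 = 1 + 3 * p.max_arm_mismatches * len(p.allowed_arm2_mismatch_positions)
    total = len(arms) * n_spacers * per_arm2
    if total > cap:
        raise ValueError(
            f"enumeration of {total} windows exceeds cap {cap}; use sampling instead"
        )
    spacers = list(_admissible_spacers(p.spacer_len, p.max_spacer_gc))
    out: set[str] = set()
    for arm1 in arms:
        arm2s = {expected_arm2(arm1)}
        if p.max_arm_mismatches:
            base = expected_arm2(arm1)
            for pos in p.allowed_arm2_mismatch_positions:
                for alt in "ACGT":
                    if alt != base[pos - 1]:
                        arm2s.add(base[: pos - 1] + alt + base[pos:])
        for spacer in spacers:
            for arm2 in arm2s:
                out.add(arm1 + spacer + arm2)
    return out
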