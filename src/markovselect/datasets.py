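"""Small built-in datasets.

The two-game free-throw example (`+` make, `-` miss) that the package
documentation walks through: two trajectories of 7 and 11 shots whose
order-1 counts, MLEs and criterion values are worked out by hand in the
docs and asserted in the test suite.
"""

from __future__ import annotations

from .simulate import FREE_THROW_ALPHABET
from .trajectories import TrajectorySet, parse_trajectories

#: Two games of free throws; alphabet ordered ("-", "+") so count
#: vectors read [misses, makes].
FREE_THROW_EXAMPLE_TEXT = "+-++-++\n+--+-+++++-\n"


def free_throw_example() -> TrajectorySet:
    """The built-in two-game free-throw example (J=2, lengths 7 and 11)."""
    return parse_trajectories(FREE_THROW_EXAMPLE_TEXT, FREE_THROW_ALPHABET)
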