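"""Exception types raised across the screening pipeline."""


class NeoscreenError(Exception):
    """Base class for all package-specific errors."""


class ReferenceMismatchError(NeoscreenError):
    """The stated reference residue does not match the protein sequence."""

    def __init__(self, protein_id: str, position: int, expected: str, found: str):
        self.protein_id = protein_id
        self.position = position
        self.expected = expected
        self.found = found
        super().__init__(
            f"reference mismatch in {protein_id!r} at position {position}: "
            f"expected {expected!r}, found {found!r}"
        )


class InvalidWellError(NeoscreenError):
    """A well readout cannot be converted into an RFU ratio (e.g. donor channel <= 0)."""


class PlateInvalidError(NeoscreenError):
    """Plate-level normalization is impossible (bad or missing negative controls)."""


class DegeneratePlateError(NeoscreenError):
    """Negative controls carry no dispersion at all; robust Z-scores are undefined."""


class UndefinedZFactorError(NeoscreenError):
    """Z-factor is undefined because control group means coincide."""


class PoolCapacityError(NeoscreenError):
    """More items than distinct k-of-n pool combinations."""

    def __init__(self, n_items: int, n_pools: int, k: int, capacity: int):
        self.n_items = n_items
        self.n_pools = n_pools
        self.k = k
        self.capacity = capacity
        super().__init__(
            f"{n_items} items exceed the C({n_pools},{k}) = {capacity} "
            f"distinct pool combinations"
        )
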