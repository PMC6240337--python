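"""Exception hierarchy shared across the molshape pipeline."""


class MolshapeError(Exception):
    """Base class for all molshape errors."""


class BadParameter(MolshapeError):
    """A parameter is outside its documented domain."""


class NoForeground(MolshapeError):
    """A binary mask contains no foreground cells."""


class DegenerateShape(MolshapeError):
    """A shape has no usable first-harmonic ellipse (null outline)."""


class MixedBasis(MolshapeError):
    """EFA coefficient sets with differing harmonic count or normalization."""


class DegenerateMatrix(MolshapeError):
    """A shape matrix with zero total variance cannot be decomposed."""


class BadGrouping(MolshapeError):
    """Group labels do not define the required number of levels."""


class SingularSystem(MolshapeError):
    """Thin-plate-spline control points are degenerate."""


class ParseError(MolshapeError):
    """Malformed Newick input; message carries position information."""


class EmptyIntersection(MolshapeError):
    """Pruning would retain no tips."""


class SingularCovariance(MolshapeError):
    """The Brownian-motion tip covariance is singular."""


class NonUltrametric(MolshapeError):
    """An operation requiring an ultrametric tree received a non-ultrametric one."""


class ConvergenceFailure(MolshapeError):
    """Iterative solver failed to converge within its iteration cap."""


class BadSequence(MolshapeError):
    """A peptide sequence is empty or contains non-standard residues."""


class TooFewSamples(MolshapeError):
    """A statistical test received fewer observations than it requires."""


class LengthMismatch(MolshapeError):
    """Paired vectors have different lengths."""
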