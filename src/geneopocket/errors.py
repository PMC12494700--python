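"""Exception hierarchy.

Every failure mode raised by the library derives from :class:`GeneoError` so
callers (and the CLI) can map error categories to exit codes.
"""


class GeneoError(Exception):
    """Base class for all geneopocket errors."""


# --- structure I/O -------------------------------------------------------

class PDBParseError(GeneoError):
    """Malformed PDB content; message names the offending line number."""


class EmptyStructureError(GeneoError):
    """No atoms survived parsing/filtering."""


class UnknownLigandError(GeneoError):
    """Ligand selector matched nothing (or AUTO found no candidate)."""


class NoChainNearLigandError(GeneoError):
    """No protein chain has an atom within the cutoff of the ligand."""


class UnknownElementError(GeneoError):
    """An atom's element is missing from the parameter table."""


# --- grids & channels ----------------------------------------------------

class GridTooLargeError(GeneoError):
    """Requested grid exceeds the voxel-count cap."""


class InvalidFieldError(GeneoError):
    """A scalar field contains NaN or infinity."""


class EmptyTruthError(GeneoError):
    """Ligand lies entirely outside the grid: truth mask would be empty."""


class EmptySpaceError(GeneoError):
    """Empty-space mask has no voxels; output normalization undefined."""


# --- model ---------------------------------------------------------------

class ParameterFloorError(GeneoError):
    """Kernel shape parameter below the resolvable floor (0.25 * spacing)."""


class KernelTooLargeError(GeneoError):
    """Convolution kernel larger than the field it is applied to."""


class InvalidWeightsError(GeneoError):
    """Combination weights are off the probability simplex."""


# --- training & evaluation ----------------------------------------------

class DegenerateDenominatorError(GeneoError):
    """Volumetric loss undefined: empty truth with k = 0."""


class DegenerateTruthError(GeneoError):
    """Overlap undefined for an empty ground-truth mask."""


class TrainingDivergedError(GeneoError):
    """Non-finite gradient or loss encountered during optimization."""


class ConfigError(GeneoError):
    """Invalid training/run configuration."""


class FixtureSpecError(GeneoError):
    """Synthetic-fixture specification is infeasible or degenerate."""
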