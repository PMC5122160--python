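"""Exception hierarchy for the conversion pipeline."""


class Cif2PrintError(Exception):
    """Base class for all pipeline errors."""


class CifParseError(Cif2PrintError):
    """CIF text could not be turned into a usable structure record."""


class NoCellError(CifParseError):
    """No data block carried a complete set of cell parameters."""


class NoAtomsError(CifParseError):
    """No data block carried an atom-site loop."""


class SymopParseError(Cif2PrintError):
    """An xyz symmetry-operator string is outside the accepted grammar."""


class InvalidCellError(Cif2PrintError):
    """Cell parameters describe a degenerate (zero/negative volume) cell."""


class DegenerateBondError(Cif2PrintError):
    """A bond cylinder was requested between coincident endpoints."""


class MeshValidationError(Cif2PrintError):
    """A shell failed the printability validation and writing was refused."""


class CorruptStlError(Cif2PrintError):
    """An STL file is truncated or its declared size disagrees with its body."""
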