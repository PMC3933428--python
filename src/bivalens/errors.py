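"""Exception and warning types used across the package."""


class BivalensError(Exception):
    """Base class for all package-specific errors."""


class PDBParseError(BivalensError):
    """Malformed PDB content; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class TopologyError(BivalensError):
    """Atom identity sequence differs between ensemble frames."""


class FormatError(BivalensError):
    """Value cannot be represented in the fixed-column PDB format."""


class EmptySelectionError(BivalensError):
    """A selection matched zero atoms (silent empties corrupt RMSD/SASA)."""


class PairingError(BivalensError):
    """Two atom lists that must be identity-matched are not."""


class DegenerateGeometryError(BivalensError):
    """Point configuration too degenerate for a unique superposition."""


class RadiusAssignmentError(BivalensError):
    """Element missing from the radius table with defaults disabled."""


class RejectedBuildError(BivalensError):
    """A constructed conformation violated the interface-preservation check."""

    def __init__(self, message: str, lost_contacts: list | None = None):
        self.lost_contacts = lost_contacts or []
        super().__init__(message)


class DockQualityWarning(UserWarning):
    """Superposition fit RMSD exceeded the configured ceiling (not fatal)."""


class DegenerateGeometryWarning(UserWarning):
    """Two atoms share identical coordinates; areas remain defined."""
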