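"""Multichannel pore-block pharmacology.

A compound is a set of per-channel Hill block profiles over the CiPA channel
panel (Nav1.5 peak/late, Cav1.2, hERG, Kv4.3, KCNQ1/KCNE1, Kir2.1).  Drug
action is simple conductance scaling: at concentration ``c`` the targeted
maximal conductance is multiplied by the remaining fraction

    scale = 1 / (1 + (c / IC50)**h)

with no state-dependent or kinetic binding.  The default concentration is the
compound's effective free therapeutic plasma concentration (EFTPC).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from importlib import resources

import yaml

from .model_core import ModelParameters

logger = logging.getLogger(__name__)

__all__ = [
    "CHANNEL_PANEL",
    "ChannelBlock",
    "DrugSpec",
    "DrugLibraryError",
    "block_fraction",
    "apply_drug",
    "load_drug_library",
    "save_drug_library",
    "shipped_library",
    "get_drug",
]

# The CiPA channel panel; each label maps to exactly one model conductance
# (see the per-model channel maps, e.g. I_Kr <- hERG).
CHANNEL_PANEL = (
    "Nav1.5-peak",
    "Nav1.5-late",
    "Cav1.2",
    "hERG",
    "Kv4.3",
    "KCNQ1/KCNE1",
    "Kir2.1",
)

HILL_MAX = 4.0


class DrugLibraryError(ValueError):
    """Schema violation in a drug-library file (carries entry/field context)."""


@dataclass(frozen=True)
class ChannelBlock:
    ic50: float          # uM
    hill: float = 1.0

    def __post_init__(self):
        if not self.ic50 > 0:
            raise DrugLibraryError(f"ic50 must be > 0, got {self.ic50}")
        if not 0 < self.hill <= HILL_MAX:
            raise DrugLibraryError(
                f"hill must be in (0, {HILL_MAX}], got {self.hill}")


@dataclass(frozen=True)
class DrugSpec:
    """One compound: EFTPC plus per-channel Hill block parameters."""

    name: str
    eftpc: float                         # uM
    blocks: dict[str, ChannelBlock] = field(default_factory=dict)

    def __post_init__(self):
        if not self.eftpc > 0:
            raise DrugLibraryError(
                f"{self.name}: eftpc must be > 0, got {self.eftpc}")
        if not self.blocks:
            raise DrugLibraryError(f"{self.name}: at least one channel entry")
        for ch in self.blocks:
            if ch not in CHANNEL_PANEL:
                raise DrugLibraryError(
                    f"{self.name}: unknown channel label {ch!r}; "
                    f"expected one of {CHANNEL_PANEL}")

    def scale_at(self, channel: str, conc: float) -> float:
        """Remaining-conductance fraction for one channel (1.0 if untargeted)."""
        blk = self.blocks.get(channel)
        if blk is None:
            return 1.0
        return block_fraction(conc, blk.ic50, blk.hill)


def block_fraction(conc: float, ic50: float, hill: float = 1.0) -> float:
    """Remaining-conductance fraction of a Hill pore block, in (0, 1].

    Monotonically non-increasing in concentration; conc = IC50 gives exactly
    0.5 for any Hill coefficient.
    """
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    if not ic50 > 0:
        raise ValueError(f"ic50 must be > 0, got {ic50}")
    if not 0 < hill <= HILL_MAX:
        raise ValueError(f"hill must be in (0, {HILL_MAX}], got {hill}")
    if conc == 0.0:
        return 1.0
    return 1.0 / (1.0 + (conc / ic50) ** hill)


def apply_drug(params: ModelParameters, drug: DrugSpec,
               conc: float | None = None) -> ModelParameters:
    """Return a copy of ``params`` with each targeted conductance scaled by
    its remaining fraction at concentration ``conc`` (default: the drug's
    EFTPC).  The input parameter set is untouched.

    A drug that targets a channel the model does not carry (per the model's
    channel map) is rejected, naming the channel.
    """
    if conc is None:
        conc = drug.eftpc
    if conc < 0:
        raise ValueError(f"concentration must be >= 0, got {conc}")
    updates: dict[str, float] = {}
    for channel, blk in drug.blocks.items():
        gname = params.channel_map.get(channel)
        if gname is None:
            raise ValueError(
                f"drug {drug.name!r} targets channel {channel!r}, which model "
                f"{params.model_name!r} does not carry")
        scale = block_fraction(conc, blk.ic50, blk.hill)
        updates[gname] = params[gname] * scale
    if not updates:
        return params
    return params.replace(**updates)


# ---------------------------------------------------------------------------
# Library file I/O (YAML; strict schema)
# ---------------------------------------------------------------------------

def _parse_entry(idx: int, entry: dict) -> DrugSpec:
    where = f"drug entry {idx}"
    if not isinstance(entry, dict):
        raise DrugLibraryError(f"{where}: expected a mapping")
    name = entry.get("name")
    if not name:
        raise DrugLibraryError(f"{where}: missing 'name'")
    where = f"drug {name!r}"
    if "eftpc_uM" not in entry:
        raise DrugLibraryError(f"{where}: missing 'eftpc_uM'")
    try:
        eftpc = float(entry["eftpc_uM"])
    except (TypeError, ValueError):
        raise DrugLibraryError(f"{where}: eftpc_uM must be a number")
    channels = entry.get("channels")
    if not isinstance(channels, dict) or not channels:
        raise DrugLibraryError(f"{where}: missing/empty 'channels' mapping")
    blocks: dict[str, ChannelBlock] = {}
    for ch, spec in channels.items():
        if ch not in CHANNEL_PANEL:
            raise DrugLibraryError(
                f"{where}: unknown channel label {ch!r}; expected one of "
                f"{CHANNEL_PANEL}")
        if not isinstance(spec, dict) or "ic50_uM" not in spec:
            raise DrugLibraryError(f"{where}/{ch}: missing 'ic50_uM'")
        ic50 = float(spec["ic50_uM"])
        if not ic50 > 0:
            raise DrugLibraryError(f"{where}/{ch}: ic50_uM must be > 0")
        if "hill" in spec and spec["hill"] is not None:
            hill = float(spec["hill"])
        else:
            hill = 1.0
            logger.info("%s/%s: no Hill coefficient; defaulting to 1.0",
                        name, ch)
        blocks[ch] = ChannelBlock(ic50=ic50, hill=hill)
    try:
        return DrugSpec(name=str(name), eftpc=eftpc, blocks=blocks)
    except DrugLibraryError as err:
        raise DrugLibraryError(f"{where}: {err}") from None


def load_drug_library(path) -> list[DrugSpec]:
    """Read a drug-library YAML file into a list of :class:`DrugSpec`.

    An empty file yields an empty library (with a warning); schema errors
    raise :class:`DrugLibraryError` naming the entry and field.
    """
    with open(path) as fh:
        doc = yaml.safe_load(fh)
    if doc is None:
        logger.warning("drug library %s is empty", path)
        return []
    entries = doc.get("drugs") if isinstance(doc, dict) else None
    if entries is None:
        raise DrugLibraryError("library file must contain a top-level 'drugs' list")
    if not entries:
        logger.warning("drug library %s contains no drugs", path)
        return []
    return [_parse_entry(i, e) for i, e in enumerate(entries)]


def save_drug_library(drugs: list[DrugSpec], path) -> None:
    doc = {"drugs": [
        {
            "name": d.name,
            "eftpc_uM": d.eftpc,
            "channels": {
                ch: {"ic50_uM": blk.ic50, "hill": blk.hill}
                for ch, blk in d.blocks.items()
            },
        }
        for d in drugs
    ]}
    with open(path, "w") as fh:
        fh.write("# cardioprofile drug library (concentrations in uM)\n")
        yaml.safe_dump(doc, fh, sort_keys=False)


def shipped_library() -> list[DrugSpec]:
    """The 12-compound CiPA training library shipped with the package."""
    ref = resources.files("cardioprofile").joinpath("data", "cipa_library.yaml")
    with resources.as_file(ref) as p:
        return load_drug_library(p)


def get_drug(name: str, library: list[DrugSpec] | None = None) -> DrugSpec:
    lib = library if library is not None else shipped_library()
    for d in lib:
        if d.name.lower() == name.lower():
            return d
    raise KeyError(f"drug {name!r} not in library "
                   f"({sorted(d.name for d in lib)})")
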