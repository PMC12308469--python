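"""Registry of the twelve Tox21 nuclear-receptor / stress-response endpoints.

Each endpoint is a binary high-throughput assay readout (1 = active,
0 = inactive) from the Tox21 program. The dataset sizes recorded here are
the per-endpoint compound counts of the public Tox21 challenge data; they
are documentation constants, not data the package ships.
"""
from __future__ import annotations

from dataclasses import dataclass

from .errors import RegistryError


@dataclass(frozen=True)
class EndpointInfo:
    code: str
    description: str
    n_compounds: int


_ENDPOINT_LIST = [
    EndpointInfo("AhR", "agonism of the aryl hydrocarbon receptor", 1901),
    EndpointInfo("AR", "antagonism of the androgen receptor", 757),
    EndpointInfo("AR-LBD", "binding to the androgen receptor ligand-binding domain", 605),
    EndpointInfo("ARE", "agonism of the antioxidant response element", 2189),
    EndpointInfo("Aromatase", "inhibition of aromatase", 713),
    EndpointInfo("ATAD5", "antagonism of the ATAD5 DNA-repair protein", 675),
    EndpointInfo("ER", "agonism of the estrogen receptor alpha", 1867),
    EndpointInfo("ER-LBD", "binding to the estrogen receptor ligand-binding domain", 883),
    EndpointInfo("HSE", "agonism of the heat shock response element", 851),
    EndpointInfo("MMP", "disruption of the mitochondrial membrane / metalloproteinase assay", 2247),
    EndpointInfo("p53", "activation of the p53 pathway", 1065),
    EndpointInfo("PPARg", "agonism of peroxisome proliferator-activated receptor gamma", 443),
]

ENDPOINTS: dict[str, EndpointInfo] = {e.code: e for e in _ENDPOINT_LIST}

#: Total number of labeled data points across the twelve endpoint datasets.
REPORTED_TOTAL_COMPOUNDS = 14196


def get_endpoint(code: str) -> EndpointInfo:
    """Look up an endpoint by code, raising :class:`RegistryError` if unknown."""
    try:
        return ENDPOINTS[code]
    except KeyError:
        raise RegistryError(
            f"unknown endpoint {code!r}; registered endpoints: {sorted(ENDPOINTS)}"
        ) from None


def registry_total() -> int:
    """Sum of the per-endpoint dataset sizes."""
    return sum(e.n_compounds for e in ENDPOINTS.values())
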