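"""Loaders for the shipped configuration catalogs.

Two catalogs ship with the package as plain YAML so that coordinates and
residues are data, not code:

* the MDP locus catalog (reference sORF per locus; see
  ``data/mdp_catalog_synthetic.yaml`` — a synthetic human-like stand-in,
  as documented in that file's header);
* the candidate amino-acid site catalog for cold-adaptation /
  high-altitude screening.

Both loaders accept a path to a user-supplied catalog of the same shape.
"""

from __future__ import annotations

from importlib import resources
from pathlib import Path

import yaml

from .comparative import CandidateSiteSpec
from .mdp_scan import LocusSpec

__all__ = ["default_mdp_catalog_path", "load_mdp_catalog", "load_sites_catalog"]


def _packaged(name: str):
    return resources.files("mitoring.data").joinpath(name)


def default_mdp_catalog_path() -> Path:
    return Path(str(_packaged("mdp_catalog_synthetic.yaml")))


def load_mdp_catalog(path: str | Path | None = None) -> list[LocusSpec]:
    """Load (and validate) an MDP locus catalog.

    Validation is structural: every entry must translate to its stated
    peptide under its stated code and start policy (enforced by
    :class:`~mitoring.mdp_scan.LocusSpec`).
    """
    source = Path(path) if path is not None else default_mdp_catalog_path()
    data = yaml.safe_load(source.read_text())
    specs = []
    for entry in data["loci"]:
        specs.append(
            LocusSpec(
                mdp_name=entry["name"],
                host_gene=entry["host"],
                nt=entry["nt"].upper(),
                sense=entry.get("sense", "host-sense"),
                peptide=entry.get("peptide", ""),
                code=entry.get("code", "standard"),
                start_policy=entry.get("start_policy", "require_listed_start"),
            )
        )
    return specs


def load_sites_catalog(path: str | Path | None = None) -> list[CandidateSiteSpec]:
    source = Path(path) if path is not None else Path(str(_packaged("sites_catalog.yaml")))
    data = yaml.safe_load(source.read_text())
    sites = []
    for entry in data["sites"]:
        sites.append(
            CandidateSiteSpec(
                gene=entry["gene"],
                codon=int(entry["codon"]),
                reference_residue=entry.get("reference_residue"),
                variant_residues=tuple(entry.get("variant_residues", []) or ()),
                phenotype=entry.get("phenotype", ""),
                human_position=entry.get("human_position"),
            )
        )
    return sites
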