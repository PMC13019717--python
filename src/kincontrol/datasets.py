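"""Packaged model files."""

from importlib.resources import files

from .model import MetabolicModel, load_model

__all__ = ["yeast_ccm"]


def yeast_ccm() -> MetabolicModel:
    """The packaged yeast central-carbon model.

    A synthetic reconstruction of the *S. cerevisiae* central-carbon
    kinetic model scaffold (glycolysis, pentose phosphate pathway,
    fermentation/glycerol branches, TCA cycle, lumped respiration, exchange
    and per-metabolite balancing drains), curated from the iMM904
    subnetwork structure: 82 reactions, 52 metabolites, 3 compartments
    (cytosol pH 7.2, mitochondria pH 7.5, extracellular), and 4 allosteric
    reactions — PFK (ATP inhibition, inorganic-phosphate activation), PYK
    (FBP activation), G3PD1ir (inorganic-phosphate inhibition) and ICDHxm
    (AMP activation).
    """
    import json

    text = files("kincontrol").joinpath("data/yeast_ccm_synthetic.json").read_text()
    return MetabolicModel.from_dict(json.loads(text))
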