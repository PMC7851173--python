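"""Small packaged datasets."""

from importlib import resources

import pandas as pd

__all__ = ["load_deployment_summary"]


def load_deployment_summary() -> pd.DataFrame:
    """Deployment summary for the 15 satellite-tagged blue whales.

    One row per instrumented individual: tag deployment date, the number
    of filtered locations used for modelling, and tracking days within
    the study area.
    """
    with resources.files("movescape.data").joinpath("deployment_summary.csv").open() as fh:
        return pd.read_csv(fh, parse_dates=["tag_date"])
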