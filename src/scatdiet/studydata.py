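"""Bundled transcription of the captive cheetah feeding-trial schedule.

Two adult male cheetahs (Jura, fed 1700 g/day; Innis, fed 1800 g/day) were
fed six prey species in varying daily proportions during November 2017.
Quail was fed exactly once to Innis and serves as the spike diet for
estimating gut-transit bounds.

Two variants of the schedule are shipped:

``verbatim``
    Exactly the proportions as printed.  Three of them read "0.6" and make
    the daily proportions for their (date, individual) sum to more than 1,
    which is physically impossible for fractions of a fixed daily ration.

``corrected``
    The same table with every impossible "0.6" read as "0.06" (a dropped
    zero).  Under this single consistent correction every (date, individual)
    group sums to exactly 1.0.  This is the variant the pipeline uses by
    default.

Species labels are normalised to title case; Latin binomials are available
through :data:`SPECIES_LATIN`.
"""

from __future__ import annotations

from io import StringIO

import pandas as pd

__all__ = [
    "CONSUMER_TAXON",
    "SPECIES_LATIN",
    "DAILY_INTAKE_G",
    "DEGRADATION_DAYS",
    "load_study_schedule",
]

#: The consumer whose reads dominate scat amplicon libraries.
CONSUMER_TAXON = "Acinonyx jubatus"

#: Common name -> species-level taxon label used in read tables.
SPECIES_LATIN = {
    "Horse": "Equus caballus",
    "Rabbit": "Oryctolagus cuniculus",
    "Deer": "Cervus spp",
    "Quail": "Coturnix coturnix",
    "Chicken": "Gallus gallus",
    "Turkey": "Meleagris gallopavo",
}

#: Grams of food offered per day to each individual.
DAILY_INTAKE_G = {"Jura": 1700.0, "Innis": 1800.0}

#: Days after deposit on which each scat was re-subsampled (day 0 = fresh).
DEGRADATION_DAYS = (0, 3, 5, 12, 15, 20, 27, 48, 60)

# date, individual, species, proportion -- proportions exactly as printed.
_VERBATIM_CSV = """\
date,individual_id,species,proportion
03.11.2017,Jura,Deer,0.47
03.11.2017,Jura,Chicken,0.18
03.11.2017,Jura,Rabbit,0.35
04.11.2017,Jura,Deer,0.47
04.11.2017,Jura,Chicken,0.29
04.11.2017,Jura,Rabbit,0.24
05.11.2017,Jura,Deer,0.82
05.11.2017,Jura,Chicken,0.18
06.11.2017,Innis,Deer,0.56
06.11.2017,Innis,Horse,0.27
06.11.2017,Innis,Chicken,0.17
06.11.2017,Jura,Deer,0.82
06.11.2017,Jura,Chicken,0.18
07.11.2017,Innis,Horse,0.61
07.11.2017,Innis,Turkey,0.06
07.11.2017,Innis,Chicken,0.33
07.11.2017,Jura,Deer,0.82
07.11.2017,Jura,Chicken,0.18
08.11.2017,Innis,Deer,0.56
08.11.2017,Innis,Rabbit,0.6
08.11.2017,Innis,Quail,0.38
08.11.2017,Jura,Deer,0.88
08.11.2017,Jura,Chicken,0.6
08.11.2017,Jura,Rabbit,0.6
09.11.2017,Innis,Horse,0.11
09.11.2017,Innis,Rabbit,0.6
09.11.2017,Innis,Chicken,0.83
09.11.2017,Jura,Deer,0.88
09.11.2017,Jura,Horse,0.12
10.11.2017,Innis,Rabbit,0.17
10.11.2017,Innis,Chicken,0.83
10.11.2017,Jura,Deer,0.88
10.11.2017,Jura,Chicken,0.12
11.11.2017,Innis,Horse,0.33
11.11.2017,Innis,Chicken,0.67
11.11.2017,Jura,Deer,0.88
11.11.2017,Jura,Chicken,0.12
12.11.2017,Innis,Deer,0.89
12.11.2017,Innis,Chicken,0.11
12.11.2017,Jura,Deer,0.88
12.11.2017,Jura,Chicken,0.12
13.11.2017,Innis,Deer,1.0
13.11.2017,Jura,Deer,0.88
13.11.2017,Jura,Chicken,0.12
14.11.2017,Innis,Rabbit,0.22
14.11.2017,Innis,Chicken,0.78
14.11.2017,Jura,Deer,0.88
14.11.2017,Jura,Chicken,0.12
15.11.2017,Innis,Rabbit,0.22
15.11.2017,Innis,Chicken,0.78
15.11.2017,Jura,Deer,0.88
15.11.2017,Jura,Chicken,0.12
16.11.2017,Jura,Deer,0.88
16.11.2017,Jura,Chicken,0.12
17.11.2017,Jura,Deer,0.88
17.11.2017,Jura,Chicken,0.12
18.11.2017,Jura,Deer,0.88
18.11.2017,Jura,Chicken,0.12
19.11.2017,Jura,Deer,0.88
19.11.2017,Jura,Chicken,0.12
"""

# (date, individual, species) cells whose printed "0.6" is read as "0.06"
# in the corrected variant.  With these three-row-cells fixed, every
# (date, individual) group sums to exactly 1.0.
_CORRECTIONS = {
    ("2017-11-08", "Innis", "Rabbit"): 0.06,
    ("2017-11-08", "Jura", "Chicken"): 0.06,
    ("2017-11-08", "Jura", "Rabbit"): 0.06,
    ("2017-11-09", "Innis", "Rabbit"): 0.06,
}


def load_study_schedule(corrected: bool = True, latin: bool = False) -> pd.DataFrame:
    """Return the feeding schedule as a tidy DataFrame.

    Parameters
    ----------
    corrected
        If True (default), apply the documented "0.6" -> "0.06" corrections
        so that daily proportions sum to 1; if False, return the printed
        values verbatim.
    latin
        If True, replace common names by species-level taxon labels
        (:data:`SPECIES_LATIN`), matching the labels used in read tables.

    Returns
    -------
    DataFrame with columns ``date`` (datetime64), ``individual_id``,
    ``species``, ``proportion``.
    """
    df = pd.read_csv(StringIO(_VERBATIM_CSV))
    df["date"] = pd.to_datetime(df["date"], format="%d.%m.%Y")
    if corrected:
        for (date, ind, sp), value in _CORRECTIONS.items():
            mask = (
                (df["date"] == pd.Timestamp(date))
                & (df["individual_id"] == ind)
                & (df["species"] == sp)
            )
            df.loc[mask, "proportion"] = value
    if latin:
        df["species"] = df["species"].map(SPECIES_LATIN)
    return df.reset_index(drop=True)
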