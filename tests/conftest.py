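import numpy as np
import pandas as pd
import pytest

from crowdvoc.config import RunConfig
from crowdvoc.evaluate import enumerate_splits
from crowdvoc.io import CompoundSeries, ScreeningRecord, build_study
from crowdvoc.pipeline import build_feature_table
from crowdvoc.preprocess import ResidualSeries
from crowdvoc.synthetic import generate_study

T0 = np.datetime64("2014-01-10T20:00:00", "s")


def make_series(values, step_s=30, compound_id="m69.0699", unit="ppb",
                start=T0, allow_missing=False):
    values = np.asarray(values, dtype=float)
    ts = start + (np.arange(len(values)) * step_s).astype("timedelta64[s]")
    return CompoundSeries(compound_id=compound_id, timestamps=ts,
                          values=values, unit=unit, allow_missing=allow_missing)


def make_residuals(values, step_s=30, film_length_min=None, start=T0):
    values = np.asarray(values, dtype=float)
    ts = start + (np.arange(len(values)) * step_s).astype("timedelta64[s]")
    if film_length_min is None:
        film_length_min = (len(values) - 1) * step_s / 60.0
    return ResidualSeries(timestamps=ts, residuals=values,
                          film_length_min=film_length_min)


def make_record(start=T0, minutes=100, viewers=100, film="film-a",
                age_class=0, sid="S0000", **kw):
    start = pd.Timestamp(start)
    return ScreeningRecord(
        screening_id=sid, film_title=film, age_class=age_class,
        room_id="room1", start_time=start,
        end_time=start + pd.Timedelta(minutes=minutes),
        viewer_count=viewers, **kw)


def pipeline_features(spec, min_test_screenings=8):
    """Generate a study and run it through windowing + featurization."""
    records, tables = generate_study(spec)
    study = build_study(records, tables)
    cfg = RunConfig(metadata_path="-", compound_path="-")
    feats, fits = build_feature_table(study, cfg, tables)
    plan = enumerate_splits(study.active_screenings(), min_test_screenings)
    return feats, plan, fits


@pytest.fixture(scope="session")
def toy_metadata_file(tmp_path_factory):
    path = tmp_path_factory.mktemp("meta") / "screenings.tsv"
    path.write_text(
        "screening_id\tfilm_title\tage_class\troom_id\tstart_time\tend_time"
        "\tviewer_count\tunder12_count\texcluded\n"
        "S0\tBuddy\t6\troom1\t2014-01-10 20:00:00\t2014-01-10 21:34:00\t80\t10\t0\n"
        "S1\tBuddy\t6\troom1\t2014-01-11 20:00:00\t2014-01-11 21:34:00\t95\t\t0\n"
        "S2\tI'm off then\t0\troom2\t2014-01-11 17:30:00\t2014-01-11 19:02:00\t120\t0\t0\n"
    )
    return path
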