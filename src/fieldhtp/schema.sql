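-- fieldhtp store schema: Staging -> Production -> Public areas.
-- Geospatial columns are paired easting/northing numerics plus zone so an
-- embedded engine suffices; the DDL stays portable to a PostgreSQL server.

CREATE TABLE IF NOT EXISTS sensorrun (
    run_id          TEXT PRIMARY KEY,
    collected_date  TEXT,
    collected_time  TEXT,
    field_id        TEXT,
    operator        TEXT,
    boom_height_s   REAL,
    wheel_spacing   REAL,
    notes           TEXT,
    loaded_at       TEXT NOT NULL,
    version         TEXT NOT NULL,
    file_inventory  TEXT NOT NULL   -- JSON: [{file, sha256}, ...]
);

-- Transient load area; emptied by promotion.
CREATE TABLE IF NOT EXISTS staging_sensorrun (
    run_id          TEXT PRIMARY KEY,
    collected_date  TEXT,
    collected_time  TEXT,
    field_id        TEXT,
    operator        TEXT,
    boom_height_s   REAL,
    wheel_spacing   REAL,
    notes           TEXT,
    file_inventory  TEXT NOT NULL
);

CREATE TABLE IF NOT EXISTS staging_observation (
    obs_id       TEXT NOT NULL,
    run_id       TEXT NOT NULL,
    sensor_id    TEXT NOT NULL,
    sensor_type  TEXT NOT NULL,
    boom_arm     TEXT,
    logger_time  TEXT NOT NULL,
    trait        TEXT NOT NULL,
    raw1         REAL,
    raw2         REAL,
    raw3         REAL,
    value        REAL,
    flag         TEXT,
    vehicle_e    REAL,
    vehicle_n    REAL,
    sensor_e     REAL,
    sensor_n     REAL,
    utm_zone     INTEGER,
    hemisphere   TEXT,
    plot_id      TEXT,
    yaw          REAL,
    pitch        REAL,
    roll         REAL,
    PRIMARY KEY (run_id, obs_id)
);

CREATE TABLE IF NOT EXISTS production_observation (
    obs_id       TEXT NOT NULL,
    run_id       TEXT NOT NULL REFERENCES sensorrun(run_id),
    sensor_id    TEXT NOT NULL,
    sensor_type  TEXT NOT NULL,
    boom_arm     TEXT,
    logger_time  TEXT NOT NULL,
    trait        TEXT NOT NULL,
    raw1         REAL,
    raw2         REAL,
    raw3         REAL,
    value        REAL,
    flag         TEXT,
    vehicle_e    REAL,
    vehicle_n    REAL,
    sensor_e     REAL,
    sensor_n     REAL,
    utm_zone     INTEGER,
    hemisphere   TEXT,
    plot_id      TEXT,
    yaw          REAL,
    pitch        REAL,
    roll         REAL,
    PRIMARY KEY (run_id, obs_id)
);

CREATE INDEX IF NOT EXISTS idx_production_run
    ON production_observation (run_id, sensor_type);

-- Public area: read-only views over production joined to run metadata.
CREATE VIEW IF NOT EXISTS public_observation AS
    SELECT p.*, s.collected_date, s.field_id, s.operator
    FROM production_observation p
    JOIN sensorrun s USING (run_id);

CREATE VIEW IF NOT EXISTS public_ultrasonic AS
    SELECT * FROM public_observation WHERE sensor_type = 'ultrasonic';
CREATE VIEW IF NOT EXISTS public_irt AS
    SELECT * FROM public_observation WHERE sensor_type = 'irt';
CREATE VIEW IF NOT EXISTS public_reflectance AS
    SELECT * FROM public_observation WHERE sensor_type = 'reflectance';
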