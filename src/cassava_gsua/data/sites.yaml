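# Two packaged study-site climate profiles: a cool highland site and a
# warm lowland site, described by growing-season mean statistics.
cool:
  name: cool-highland
  latitude: 2.4278
  longitude: -76.6208
  altitude: 1750
  season_mean_temp: 18.0
  season_mean_srad: 16.0
  season_rainfall: 890.0
  diurnal_range: 11.0
  wet_day_freq: 0.45
warm:
  name: warm-lowland
  latitude: 8.8397
  longitude: -75.8019
  altitude: 20
  season_mean_temp: 28.0
  season_mean_srad: 17.0
  season_rainfall: 1130.0
  diurnal_range: 10.0
  wet_day_freq: 0.40
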