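{
  "_comment": "Synthetic 11-region lattice bounding boxes (lon_min, lon_max, lat_min, lat_max), degrees. A stand-in geometry for simulation only: region labels follow the 2016 Ethiopia DHS regions but the cells are an abstract grid, not real boundaries.",
  "Tigray": [33.0, 36.0, 12.0, 15.0],
  "Afar": [36.0, 39.0, 12.0, 15.0],
  "Dire Dawa": [39.0, 42.0, 12.0, 15.0],
  "Harari": [42.0, 45.0, 12.0, 15.0],
  "Benishangul": [33.0, 36.0, 9.0, 12.0],
  "Amhara": [36.0, 39.0, 9.0, 12.0],
  "Addis Ababa": [39.0, 42.0, 9.0, 12.0],
  "Somali": [42.0, 45.0, 9.0, 12.0],
  "Gambela": [33.0, 36.0, 6.0, 9.0],
  "SNNPR": [36.0, 39.0, 6.0, 9.0],
  "Oromia": [39.0, 42.0, 6.0, 9.0]
}
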