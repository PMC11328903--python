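# Default migration-waypoint configuration for out-of-Africa distance
# calculation.  Distances are summed over great-circle legs
# origin -> waypoints(path) -> population.
#
# These coordinates are a plausible editable default approximating the
# overland expansion corridors commonly used in dental and craniometric
# cline studies (Nile corridor / Levant into Eurasia, Bering land bridge
# into the Americas, Sunda-Sahul into Oceania).  Review and edit them for
# any serious application; tests use synthetic routes only.
origin: {name: sub_saharan_africa, latitude: 0.0, longitude: 25.0}
waypoints:
  cairo: {latitude: 30.0, longitude: 31.2}
  istanbul: {latitude: 41.0, longitude: 28.9}
  tehran: {latitude: 35.7, longitude: 51.4}
  delhi: {latitude: 28.6, longitude: 77.2}
  hanoi: {latitude: 21.0, longitude: 105.8}
  bering: {latitude: 65.5, longitude: -169.0}
  anchorage: {latitude: 61.2, longitude: -149.9}
  panama: {latitude: 9.0, longitude: -79.5}
  phuket: {latitude: 8.0, longitude: 98.3}
paths:
  africa: []
  europe: [cairo, istanbul]
  west_asia: [cairo, tehran]
  east_asia: [cairo, tehran, delhi, hanoi]
  oceania: [cairo, tehran, delhi, phuket]
  north_america: [cairo, tehran, delhi, hanoi, bering, anchorage]
  south_america: [cairo, tehran, delhi, hanoi, bering, anchorage, panama]
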