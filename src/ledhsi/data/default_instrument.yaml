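# Default instrument: 18-channel LED array (405-910 nm) around a
# 1280x720 monochrome camera (120 fps max, 90 deg FOV).
led_ring_radius_mm: 6.0
leds:
  - {wavelength_nm: 405, half_width_nm: 19, viewing_angle_deg: 102}
  - {wavelength_nm: 420, half_width_nm: 16, viewing_angle_deg: 26}
  - {wavelength_nm: 450, half_width_nm: 20, viewing_angle_deg: 40}
  - {wavelength_nm: 470, half_width_nm: 25, viewing_angle_deg: 80}
  - {wavelength_nm: 505, half_width_nm: 30, viewing_angle_deg: 86}
  - {wavelength_nm: 525, half_width_nm: 30, viewing_angle_deg: 18}
  - {wavelength_nm: 555, half_width_nm: 25, viewing_angle_deg: 40}
  - {wavelength_nm: 590, half_width_nm: 13, viewing_angle_deg: 64}
  - {wavelength_nm: 610, half_width_nm: 15, viewing_angle_deg: 30}
  - {wavelength_nm: 630, half_width_nm: 15, viewing_angle_deg: 60}
  - {wavelength_nm: 660, half_width_nm: 18, viewing_angle_deg: 80}
  - {wavelength_nm: 700, half_width_nm: 21, viewing_angle_deg: 80}
  - {wavelength_nm: 770, half_width_nm: 26, viewing_angle_deg: 14}
  - {wavelength_nm: 800, half_width_nm: 29, viewing_angle_deg: 88}
  - {wavelength_nm: 830, half_width_nm: 35, viewing_angle_deg: 14}
  - {wavelength_nm: 850, half_width_nm: 40, viewing_angle_deg: 26}
  - {wavelength_nm: 890, half_width_nm: 75, viewing_angle_deg: 40}
  - {wavelength_nm: 910, half_width_nm: 47, viewing_angle_deg: 30}
camera:
  rows: 720
  cols: 1280
  bit_depth: 10
  fps_max: 120
  angular_fov: 90
timing:
  pw_frames: 1
  dt_frames: 1
link:
  rate_mbps: 400
  unit: binary
geometry:
  working_distance: 70.0
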