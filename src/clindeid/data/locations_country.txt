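Argentina
Perú
Bolivia
Colombia
Venezuela
Ecuador
Paraguay
Uruguay
Brasil
México
Haití
España
Cuba
Honduras
Nicaragua
Guatemala
Panamá
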