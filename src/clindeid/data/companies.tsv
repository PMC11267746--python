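Constructora Los Andes Ltda.	una constructora
Constructora Pacífico SpA	una constructora
Edificaciones del Sur S.A.	una constructora
Minera Cordillera S.A.	una minera
Minera del Norte SpA	una minera
Agrícola Valle Verde Ltda.	una empresa agrícola
Agroindustrial El Huerto S.A.	una empresa agrícola
Frutícola Maipo Ltda.	una empresa agrícola
Forestal Arauco del Sur S.A.	una forestal
Maderas y Aserríos Bío Bío Ltda.	una forestal
Pesquera Mar Austral S.A.	una pesquera
Salmones del Canal SpA	una pesquera
Transportes Ruta Cinco Ltda.	una empresa de transporte
Logística Andina SpA	una empresa de transporte
Buses Interurbanos del Sur S.A.	una empresa de transporte
Supermercados La Canasta S.A.	un supermercado
Distribuidora Central Ltda.	una distribuidora
Comercial El Trébol Ltda.	un comercio
Ferretería El Tornillo Ltda.	un comercio
Panificadora La Espiga S.A.	una empresa de alimentos
Alimentos del Campo SpA	una empresa de alimentos
Elaboradora de Alimentos Australes S.A.	una empresa de alimentos
Colegio Cumbres del Valle	un centro educativo
Escuela Básica Los Castaños	un centro educativo
Instituto Técnico Horizonte	un centro educativo
Aseo Industrial Impecable Ltda.	una empresa de aseo
Servicios de Limpieza Total SpA	una empresa de aseo
Seguridad Centinela Ltda.	una empresa de seguridad
Metalúrgica Aceros del Pacífico S.A.	una empresa metalúrgica
Maestranza El Yunque Ltda.	una empresa metalúrgica
Textiles del Maule S.A.	una empresa textil
Restaurante El Fogón Criollo	un restaurante
Hotel Mirador del Lago	un hotel
Clínica Dental Sonrisa Plena	un centro de salud
Envases Plásticos del Centro SpA	una empresa manufacturera
Imprenta Gráfica Moderna Ltda.	una empresa manufacturera
Energía Eólica del Norte S.A.	una empresa de energía
Sanitarias Aguas Claras S.A.	una empresa sanitaria
Telecomunicaciones Conecta SpA	una empresa de telecomunicaciones
Inmobiliaria Altos del Parque S.A.	una inmobiliaria
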